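"""Synthetic behavioral and neural sessions with planted ground truth.

The generator emulates the head-fixed two-alternative categorization
task: each trial runs through an inter-trial interval, a no-lick/no-run
period, 1.5 s of stimulus, a 0.2 s delay and a 10 s response window in
which the first lick on either spout decides the trial. Timing jitter
(the task's "x +- j s" periods) is sampled uniformly over +- j. An
artificial agent chooses sides through a logistic function of the
stimulus' signed distance to its own, planted category boundary, with
a lapse rate, a side bias and a configurable miss probability.

Neural activity is generated from the same design-matrix machinery the
encoding GLM uses: every neuron owns a set of nonnegative planted
kernels (weights over time offsets, per regressor set and level), the
full-session design matrix is multiplied by those weights, per-trial
gain variability and rectified Gaussian noise are applied, and the
result is clipped at zero -- a nonnegative inferred-spike trace in
spikes/s. With noise and gain variability at zero, the design matrix
applied to the planted weights reproduces the activity exactly, which
is the anchor for all recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import (
    DesignMatrix,
    RegressorSet,
    build_design_matrix,
    default_regressor_sets,
    smooth_trace,
)
from .session import SessionRecording
from .spaces import CategorySpace, signed_boundary_distance

__all__ = [
    "AgentParams",
    "TimingConfig",
    "PlantedKernels",
    "simulate_behavior_session",
    "simulate_neural_session",
    "simulate_fluorescence",
    "random_planted_kernels",
    "FluorescenceTraces",
]


@dataclass
class AgentParams:
    """Choice policy of the simulated animal.

    The agent picks "right" with probability
    ``lapse/2 + (1 - lapse) * logistic(steepness * (d + side_bias))``
    where ``d`` is the stimulus' signed grid distance to the agent's
    planted boundary. ``steepness = inf`` gives a perfect step
    categorizer; ``side_bias`` shifts the effective boundary by that
    many grid units toward one side.
    """

    planted_boundary_angle_deg: float = 45.0
    planted_boundary_offset: float = 0.0
    lapse_rate: float = 0.0
    side_bias: float = 0.0
    steepness: float = np.inf
    miss_probability: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate must be in [0, 1]")
        if not -1.0 <= self.side_bias <= 1.0:
            raise ValueError("side_bias must be in [-1, 1]")
        if not self.steepness > 0:
            raise ValueError("steepness must be > 0")
        if not 0.0 <= self.miss_probability <= 1.0:
            raise ValueError("miss_probability must be in [0, 1]")


@dataclass
class TimingConfig:
    """Trial-phase durations (seconds) with uniform +- jitter."""

    iti_s: float = 5.0
    iti_jitter_s: float = 0.25
    prestim_s: float = 0.7          # no-lick, no-run period
    prestim_jitter_s: float = 0.1
    stimulus_s: float = 1.5
    stimulus_jitter_s: float = 0.1
    delay_s: float = 0.2
    delay_jitter_s: float = 0.1
    response_window_s: float = 10.0
    lick_latency_min_s: float = 0.3
    lick_latency_scale_s: float = 0.5   # exponential scale of extra latency
    lick_latency_max_s: float = 3.0
    timeout_s: float = 2.0
    lead_in_s: float = 5.0
    tail_s: float = 8.0

    def jittered(self, rng: np.random.Generator, base: float, jitter: float) -> float:
        return base + rng.uniform(-jitter, jitter)


def simulate_behavior_session(
    space: CategorySpace,
    agent: AgentParams,
    n_trials: int,
    timing: TimingConfig | None = None,
    seed=None,
    run_probability: float = 0.5,
) -> pd.DataFrame:
    """Simulate one behavioral session as a trial table.

    Stimuli are drawn uniformly from the space's active, labeled
    stimuli. Events within a trial (stimulus onset/offset, choice
    licks, reward or time-out) are strictly ordered; miss trials carry
    NaN for all response events.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    timing = timing or TimingConfig()
    rng = np.random.default_rng(seed)
    active = space.active_stimuli()
    if len(active) == 0:
        raise ValueError("category space has no active labeled stimuli")

    picks = active.iloc[rng.integers(0, len(active), size=n_trials)].reset_index(drop=True)
    agent_dist = signed_boundary_distance(
        picks["ori_index"].to_numpy(dtype=float),
        picks["sf_index"].to_numpy(dtype=float),
        agent.planted_boundary_angle_deg,
        agent.planted_boundary_offset,
        space.grid_center,
    )
    arg = agent_dist + agent.side_bias
    if np.isinf(agent.steepness):
        base_p = np.where(arg > 0, 1.0, np.where(arg < 0, 0.0, 0.5))
    else:
        base_p = 1.0 / (1.0 + np.exp(-agent.steepness * arg))
    p_right = agent.lapse_rate / 2.0 + (1.0 - agent.lapse_rate) * base_p

    chose_right = rng.random(n_trials) < p_right
    missed = rng.random(n_trials) < agent.miss_probability
    choice = np.where(missed, "miss", np.where(chose_right, "right", "left"))
    correct = np.where(missed, False, choice == picks["category"].to_numpy())

    rows = []
    t = timing.lead_in_s
    for i in range(n_trials):
        t += timing.jittered(rng, timing.iti_s, timing.iti_jitter_s)
        t += timing.jittered(rng, timing.prestim_s, timing.prestim_jitter_s)
        onset = t
        offset = onset + timing.jittered(rng, timing.stimulus_s, timing.stimulus_jitter_s)
        rw_start = offset + timing.jittered(rng, timing.delay_s, timing.delay_jitter_s)
        choice_lick = response_lick = reward = timeout = np.nan
        if not missed[i]:
            latency = timing.lick_latency_min_s + min(
                rng.exponential(timing.lick_latency_scale_s),
                timing.lick_latency_max_s - timing.lick_latency_min_s,
            )
            response_lick = rw_start + latency
            # anticipatory lick run starting shortly before the decisive lick
            choice_lick = max(onset + 0.2, response_lick - rng.uniform(0.0, 0.5))
            if correct[i]:
                reward = response_lick
                t = response_lick + 1.0  # consumption period
            else:
                timeout = response_lick
                t = response_lick + timing.timeout_s
        else:
            t = rw_start + timing.response_window_s
        run_onset = np.nan
        if rng.random() < run_probability:
            run_onset = onset + rng.uniform(-1.0, 3.0)
        rows.append(
            (i, onset, offset, rw_start, choice_lick, response_lick, reward,
             timeout, run_onset, t)
        )

    times = pd.DataFrame(
        rows,
        columns=["trial_id", "stimulus_onset", "stimulus_offset",
                 "response_window_start", "choice_lick_time", "response_lick_time",
                 "reward_time", "timeout_time", "run_onset_time", "trial_end"],
    )
    trials = pd.concat(
        [
            picks[["ori_index", "sf_index", "direction", "orientation_deg",
                   "spatial_frequency", "category", "signed_distance"]],
            times,
        ],
        axis=1,
    )
    trials["agent_distance"] = agent_dist
    trials["choice"] = choice
    trials["correct"] = correct.astype(bool)
    trials["response_made"] = ~missed
    return trials


# ---------------------------------------------------------------------------
# neural sessions


@dataclass
class PlantedKernels:
    """Planted nonnegative response kernels for a population.

    ``weights`` maps a neuron index to a dict keyed by
    ``(set_label, level)`` (level "" for single-level sets) whose
    values are nonnegative weight arrays over the set's time offsets.
    The key ``("offset", "")`` holds a length-1 baseline-rate weight.
    """

    weights: list[dict[tuple[str, str], np.ndarray]]

    @property
    def n_neurons(self) -> int:
        return len(self.weights)

    def as_matrix(self, design: DesignMatrix) -> np.ndarray:
        """(n_neurons, n_columns) weight matrix aligned to a design."""
        W = np.zeros((self.n_neurons, design.n_columns))
        meta = design.columns
        index = {}
        for j, (lab, lev, off) in enumerate(
            zip(meta["set_label"], meta["level"], meta["offset_s"])
        ):
            index.setdefault((lab, str(lev)), []).append((float(off), j))
        for n, kernels in enumerate(self.weights):
            for (lab, lev), w in kernels.items():
                w = np.asarray(w, dtype=float)
                if np.any(w < 0):
                    raise ValueError("planted kernel weights must be nonnegative")
                key = (lab, str(lev))
                if key not in index:
                    raise ValueError(f"no design columns for planted kernel {key}")
                entries = sorted(index[key])
                if len(entries) != len(w):
                    raise ValueError(
                        f"kernel {key}: {len(w)} weights for {len(entries)} offsets"
                    )
                for (_, j), wj in zip(entries, w):
                    W[n, j] = wj
        return W


def _autocorrelated_noise(rng, n_frames, frame_rate_hz, tau_s, sd) -> np.ndarray:
    """Zero-mean AR(1) process with time constant ``tau_s``."""
    alpha = np.exp(-1.0 / (tau_s * frame_rate_hz))
    innov = rng.normal(0.0, sd * np.sqrt(1 - alpha**2), size=n_frames)
    out = np.empty(n_frames)
    acc = 0.0
    for i in range(n_frames):
        acc = alpha * acc + innov[i]
        out[i] = acc
    return out


def _generate_covariates(trials: pd.DataFrame, n_frames: int, frame_rate_hz: float,
                         rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Running-speed and per-spout lick-rate channels consistent with events."""
    t = np.arange(n_frames) / frame_rate_hz
    run = np.zeros(n_frames)
    for onset in trials["run_onset_time"].dropna():
        dur = rng.uniform(1.0, 3.0)
        peak = rng.uniform(5.0, 15.0)  # cm/s
        mask = (t >= onset) & (t < onset + dur)
        run[mask] += peak * np.sin(np.pi * (t[mask] - onset) / dur) ** 2
    run += _autocorrelated_noise(rng, n_frames, frame_rate_hz, tau_s=1.0, sd=0.5)
    run = np.clip(run, 0.0, None)

    lick = {"left": np.zeros(n_frames), "right": np.zeros(n_frames)}
    for _, tr in trials.iterrows():
        if not tr["response_made"]:
            continue
        side = tr["choice"]
        start = tr["choice_lick_time"]
        dur = 1.5 if np.isfinite(tr.get("reward_time", np.nan)) else 0.8
        rate = rng.uniform(4.0, 8.0)  # licks/s during a bout
        mask = (t >= start) & (t < tr["response_lick_time"] + dur)
        lick[side][mask] += rate
    for side in lick:
        lick[side] = np.clip(
            smooth_trace(lick[side], frame_rate_hz, sigma_s=0.3)
            + _autocorrelated_noise(rng, n_frames, frame_rate_hz, 0.5, 0.2),
            0.0, None,
        )
    return {
        "run_speed": run,
        "lick_rate_left": lick["left"],
        "lick_rate_right": lick["right"],
    }


def simulate_neural_session(
    trials: pd.DataFrame,
    kernels: PlantedKernels,
    frame_rate_hz: float = 15.0,
    noise_sd: float = 0.5,
    trial_gain_cv: float = 0.2,
    seed=None,
    regressor_sets: list[RegressorSet] | None = None,
    window_s: tuple[float, float] = (-1.5, 5.5),
    meta: dict | None = None,
) -> SessionRecording:
    """Generate inferred-spike activity from planted kernels.

    ``activity = clip(gain * (design @ weights) + rectified noise, 0)``
    where the design matrix is the same one the encoding GLM builds,
    ``gain`` is a per-trial multiplicative factor with coefficient of
    variation ``trial_gain_cv`` (Poisson-like trial-to-trial
    variability) and the additive noise is a rectified Gaussian with
    standard deviation ``noise_sd`` (spikes/s).
    """
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be positive")
    rng = np.random.default_rng(seed)
    if regressor_sets is None:
        regressor_sets = default_regressor_sets()

    n_frames = int(np.ceil((trials["trial_end"].iloc[-1] + 8.0) * frame_rate_hz))
    covariates = _generate_covariates(trials, n_frames, frame_rate_hz, rng)
    design = build_design_matrix(
        trials, covariates, n_frames, frame_rate_hz,
        regressor_sets=regressor_sets, window_s=window_s,
    )
    W = kernels.as_matrix(design)
    clean = W @ design.X.T  # neurons x frames

    if trial_gain_cv > 0:
        shape = 1.0 / trial_gain_cv**2
        gains = rng.gamma(shape, scale=1.0 / shape,
                          size=(kernels.n_neurons, len(trials)))
        gain_frames = np.ones((kernels.n_neurons, n_frames))
        # frames are attributed to the nearest trial: cut midway between
        # the end of one trial window and the start of the next
        ends = design.trial_starts + design.frames_per_trial
        cuts = (ends[:-1] + design.trial_starts[1:]) // 2
        bounds = np.r_[0, cuts, n_frames]
        for ti in range(len(trials)):
            gain_frames[:, bounds[ti]:bounds[ti + 1]] = gains[:, [ti]]
        clean = clean * gain_frames
    if noise_sd > 0:
        noise = np.clip(rng.normal(0.0, noise_sd, size=clean.shape), 0.0, None)
        clean = clean + noise
    activity = np.clip(clean, 0.0, None)

    full_meta = {"seed": seed, "noise_sd": noise_sd, "trial_gain_cv": trial_gain_cv,
                 "window_s": list(window_s)}
    if meta:
        full_meta.update(meta)
    full_meta["ground_truth"] = {"weights": W, "columns": design.columns.copy()}
    return SessionRecording(
        activity=activity, frame_rate_hz=frame_rate_hz,
        trials=trials.reset_index(drop=True), covariates=covariates, meta=full_meta,
    )


def random_planted_kernels(
    space: CategorySpace,
    n_neurons: int,
    seed=None,
    regressor_sets: list[RegressorSet] | None = None,
    amplitude: float = 4.0,
    baseline: float = 0.2,
) -> PlantedKernels:
    """A mixed population of planted response archetypes.

    Each neuron receives a smooth, nonnegative kernel (amplitude in
    spikes/s) for a primary coupling drawn from: orientation tuning,
    spatial-frequency tuning, category, choice, reward, or running --
    plus a small baseline rate. Used for recovery experiments where
    approximate knowledge of the archetype mix suffices; construct
    :class:`PlantedKernels` directly for exact control.
    """
    rng = np.random.default_rng(seed)
    sets = {s.label: s for s in (regressor_sets or default_regressor_sets())}
    active = space.active_stimuli()
    archetypes = ["orientation", "spatial_frequency", "category", "choice_1",
                  "reward", "run_speed"]
    weights = []
    for _ in range(n_neurons):
        kernels: dict[tuple[str, str], np.ndarray] = {
            ("offset", ""): np.array([baseline * rng.uniform(0.5, 1.5)]),
        }
        kind = archetypes[rng.integers(0, len(archetypes))]
        rset = sets[kind]
        offs = rset.offsets
        amp = amplitude * rng.uniform(0.5, 1.5)
        bump = np.exp(-0.5 * ((offs - rng.uniform(offs[0], offs[-1])) / 0.75) ** 2)
        if kind == "orientation":
            level = str(rng.choice(np.unique(active["ori_index"])))
        elif kind == "spatial_frequency":
            level = str(rng.choice(np.unique(active["sf_index"])))
        elif kind in ("category", "choice_1"):
            level = "left" if rng.random() < 0.5 else "right"
        else:
            level = ""
        kernels[(kind, level)] = amp * bump
        weights.append(kernels)
    return PlantedKernels(weights)


# ---------------------------------------------------------------------------
# raw fluorescence


@dataclass
class FluorescenceTraces:
    """Two-channel raw traces for the signal-conditioning stage."""

    signal: np.ndarray          # neurons x frames (activity channel)
    structural: np.ndarray      # neurons x frames (anatomical channel)
    neuropil: np.ndarray        # neurons x frames (annulus around each ROI)
    frame_rate_hz: float


def simulate_fluorescence(
    session: SessionRecording,
    contamination: float = 0.3,
    drift_amplitude: float = 0.0,
    drift_period_s: float = 300.0,
    calcium_tau_s: float = 0.7,
    neuropil_level: float = 1.0,
    baseline_f: float = 1.0,
    seed=None,
) -> FluorescenceTraces:
    """Render raw two-channel fluorescence from an inferred-spike session.

    The signal channel is the calcium-kernel (exponential, ``tau``)
    convolution of the spikes plus ``contamination`` x the neuropil
    trace; the structural channel is a constant per neuron. A shared
    multiplicative drift (sinusoid of ``drift_amplitude``) is applied
    to both channels and the neuropil, emulating slow z-drift that the
    ratiometric dR/R stage must cancel.
    """
    if not 0.0 <= contamination <= 1.0:
        raise ValueError("contamination must be in [0, 1]")
    rng = np.random.default_rng(seed)
    spikes = session.activity
    n_neurons, n_frames = spikes.shape
    fr = session.frame_rate_hz

    decay = np.exp(-np.arange(int(5 * calcium_tau_s * fr)) / (calcium_tau_s * fr))
    conv = np.apply_along_axis(
        lambda x: np.convolve(x, decay)[:n_frames], 1, spikes
    ) / fr

    npil = neuropil_level + 0.2 * neuropil_level * np.vstack(
        [_autocorrelated_noise(rng, n_frames, fr, 2.0, 1.0) for _ in range(n_neurons)]
    )
    npil = np.clip(npil, 0.05 * neuropil_level, None)

    t = np.arange(n_frames) / fr
    drift = 1.0 + drift_amplitude * np.sin(2 * np.pi * t / drift_period_s)

    signal = (baseline_f + conv + contamination * npil) * drift
    structural = np.full_like(signal, baseline_f) * drift
    neuropil = npil * drift
    return FluorescenceTraces(signal=signal, structural=structural,
                              neuropil=neuropil, frame_rate_hz=fr)
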