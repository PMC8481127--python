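"""Design matrices of time-shifted Gaussian kernels for the encoding GLM.

Each *regressor set* models the influence of one event type (stimulus
onset, choice licks, reward, time-out, run onset) or one continuous
covariate (lick rates, running speed) on a neuron's inferred spiking.
A set consists of one column per (event level, time offset): discrete
events are represented as unit impulses at their exact occurrence
times, rendered through a Gaussian kernel (sigma = 0.5 s, truncated at
+-3 sigma, unit area in continuous time), repeated at offsets spaced
0.5 s over the set's declared range. Continuous covariates are
smoothed with the same kernel (unit sum, amplitude preserving) and
time-shifted over their range. A constant offset column completes the
matrix.

Fitting operates on equal-length per-trial windows around stimulus
onset; only frames inside a trial window enter the fit. Windows must
not overlap so every frame belongs to at most one trial, which makes
trial-level cross-validation and trial-identity shuffles well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "KERNEL_SIGMA_S",
    "OFFSET_STEP_S",
    "RegressorSet",
    "DesignMatrix",
    "default_regressor_sets",
    "build_design_matrix",
    "gaussian_kernel",
    "smooth_trace",
]

KERNEL_SIGMA_S = 0.5    # Gaussian kernel width, seconds
OFFSET_STEP_S = 0.5     # spacing of time offsets within a set, seconds
KERNEL_TRUNC_SIGMAS = 3.0

#: subgroup vocabulary used for unique-contribution (delta R^2) analyses
SUBGROUPS = (
    "stimulus-task", "orientation", "spatial_frequency", "category",
    "choice", "reward-timeout", "movement",
)


@dataclass(frozen=True)
class RegressorSet:
    """Declaration of one regressor set.

    ``kind`` is "event" (aligned to a trial-table time column) or
    "continuous" (a covariate channel). ``level_by`` names a trial
    column whose distinct values become separate levels (e.g. one level
    per orientation); None means a single level. ``condition`` names a
    boolean trial column restricting which trials contribute events.
    """

    label: str
    kind: str
    align: str                 # event time column, or covariate name
    offset_min_s: float
    offset_max_s: float
    subgroup: str
    level_by: str | None = None
    condition: str | None = None
    #: trial epoch whose events drive this set: "stimulus" (onset-locked),
    #: "response" (lick/reward-locked, including lick-rate channels) or
    #: "locomotion". Sets within one epoch share (near-)identical event
    #: times and are inherently redundant; collinearity diagnostics
    #: compare across epochs.
    epoch: str = "stimulus"

    @property
    def offsets(self) -> np.ndarray:
        n = int(round((self.offset_max_s - self.offset_min_s) / OFFSET_STEP_S))
        return self.offset_min_s + OFFSET_STEP_S * np.arange(n + 1)


def default_regressor_sets(include_task_sets: bool = True) -> list[RegressorSet]:
    """The standard in-task regressor configuration.

    Kernel ranges (seconds, relative to the alignment event):
    stimulus-aligned sets (orientation, spatial frequency, category,
    task) 0 to +3; choice and reward/time-out sets -0.5 to +2.5; run
    onset -0.5 to +2; continuous channels -1 to +1. With
    ``include_task_sets=False`` only the stimulus-aligned sensory sets
    and running sets remain (out-of-task tuning-curve sessions).
    """
    sets = [
        RegressorSet("orientation", "event", "stimulus_onset", 0.0, 3.0,
                     "orientation", level_by="ori_index"),
        RegressorSet("spatial_frequency", "event", "stimulus_onset", 0.0, 3.0,
                     "spatial_frequency", level_by="sf_index"),
        RegressorSet("run_onset", "event", "run_onset_time", -0.5, 2.0,
                     "movement", epoch="locomotion"),
        RegressorSet("run_speed", "continuous", "run_speed", -1.0, 1.0,
                     "movement", epoch="locomotion"),
    ]
    if include_task_sets:
        sets += [
            RegressorSet("category", "event", "stimulus_onset", 0.0, 3.0,
                         "category", level_by="category"),
            RegressorSet("task", "event", "stimulus_onset", 0.0, 3.0,
                         "stimulus-task", condition="response_made"),
            RegressorSet("choice_1", "event", "choice_lick_time", -0.5, 2.5,
                         "choice", level_by="choice", epoch="response"),
            RegressorSet("choice_2", "event", "response_lick_time", -0.5, 2.5,
                         "choice", level_by="choice", epoch="response"),
            RegressorSet("reward", "event", "reward_time", -0.5, 2.5,
                         "reward-timeout", epoch="response"),
            RegressorSet("timeout", "event", "timeout_time", -0.5, 2.5,
                         "reward-timeout", epoch="response"),
            RegressorSet("lick_rate_left", "continuous", "lick_rate_left",
                         -1.0, 1.0, "movement", epoch="response"),
            RegressorSet("lick_rate_right", "continuous", "lick_rate_right",
                         -1.0, 1.0, "movement", epoch="response"),
        ]
    return sets


def gaussian_kernel(frame_rate_hz: float, sigma_s: float = KERNEL_SIGMA_S,
                    unit: str = "sum") -> np.ndarray:
    """Discretized truncated Gaussian kernel.

    ``unit="sum"`` normalizes to unit discrete sum (for smoothing,
    amplitude preserving); ``unit="area"`` scales as a probability
    density in continuous time (for rendering unit-area event
    impulses), so values are larger by the frame rate.
    """
    half = int(np.ceil(KERNEL_TRUNC_SIGMAS * sigma_s * frame_rate_hz))
    t = np.arange(-half, half + 1) / frame_rate_hz
    g = np.exp(-0.5 * (t / sigma_s) ** 2)
    if unit == "sum":
        return g / g.sum()
    if unit == "area":
        return g / g.sum() * frame_rate_hz
    raise ValueError("unit must be 'sum' or 'area'")


def smooth_trace(trace, frame_rate_hz: float, sigma_s: float = KERNEL_SIGMA_S) -> np.ndarray:
    """Centered Gaussian smoothing, edge-renormalized (no amplitude loss)."""
    x = np.asarray(trace, dtype=float)
    g = gaussian_kernel(frame_rate_hz, sigma_s, unit="sum")
    num = np.convolve(x, g, mode="same")
    den = np.convolve(np.ones_like(x), g, mode="same")
    return num / den


@dataclass
class DesignMatrix:
    """A rendered design with per-trial window bookkeeping.

    ``X`` spans the full session (frames x columns). ``columns`` has a
    row per column with ``set_label``, ``level``, ``offset_s`` and
    ``subgroup`` ("offset" for the constant column). ``trial_starts``
    holds the first frame of each equal-length trial window of
    ``frames_per_trial`` frames; the union of windows is the included
    frame set.
    """

    X: np.ndarray = field(repr=False)
    columns: pd.DataFrame = field(repr=False)
    frame_rate_hz: float
    trial_starts: np.ndarray
    frames_per_trial: int
    trial_index: pd.DataFrame = field(repr=False)  # per-trial metadata copy

    @property
    def n_trials(self) -> int:
        return len(self.trial_starts)

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    def trial_tensor(self) -> np.ndarray:
        """(n_trials, frames_per_trial, n_columns) stacked trial windows."""
        idx = self.trial_starts[:, None] + np.arange(self.frames_per_trial)[None, :]
        return self.X[idx]

    def slice_response(self, trace) -> np.ndarray:
        """(n_trials, frames_per_trial) windows of a full-session trace."""
        trace = np.asarray(trace, dtype=float)
        idx = self.trial_starts[:, None] + np.arange(self.frames_per_trial)[None, :]
        return trace[idx]

    def included_frames(self) -> np.ndarray:
        """Sorted indices of frames inside any trial window."""
        idx = self.trial_starts[:, None] + np.arange(self.frames_per_trial)[None, :]
        return idx.ravel()

    def subgroup_columns(self, subgroup: str) -> np.ndarray:
        cols = np.flatnonzero(self.columns["subgroup"].to_numpy() == subgroup)
        if len(cols) == 0:
            raise ValueError(f"unknown or empty subgroup: {subgroup!r}")
        return cols

    def set_columns(self, set_label: str) -> np.ndarray:
        return np.flatnonzero(self.columns["set_label"].to_numpy() == set_label)


def _render_events(col: np.ndarray, times: np.ndarray, offset_s: float,
                   frame_rate_hz: float, n_frames: int) -> None:
    """Add a unit-area Gaussian at each event time + offset into ``col``."""
    sigma = KERNEL_SIGMA_S
    half = KERNEL_TRUNC_SIGMAS * sigma
    scale = 1.0 / (np.sqrt(2.0 * np.pi) * sigma)
    for t in times:
        center = t + offset_s
        f0 = max(0, int(np.ceil((center - half) * frame_rate_hz)))
        f1 = min(n_frames - 1, int(np.floor((center + half) * frame_rate_hz)))
        if f1 < f0:
            continue
        ft = np.arange(f0, f1 + 1) / frame_rate_hz
        col[f0 : f1 + 1] += scale * np.exp(-0.5 * ((ft - center) / sigma) ** 2)


def _shift_trace(trace: np.ndarray, offset_s: float, frame_rate_hz: float) -> np.ndarray:
    """Shift a trace later by ``offset_s`` (linear interpolation, zero-padded)."""
    n = len(trace)
    t = np.arange(n) / frame_rate_hz
    return np.interp(t - offset_s, t, trace, left=0.0, right=0.0)


def build_design_matrix(
    trials: pd.DataFrame,
    covariates: dict[str, np.ndarray],
    n_frames: int,
    frame_rate_hz: float,
    regressor_sets: list[RegressorSet] | None = None,
    window_s: tuple[float, float] = (-1.5, 5.5),
) -> DesignMatrix:
    """Render the full design matrix for one session.

    Parameters
    ----------
    trials : DataFrame
        Trial table with event-time columns (seconds; NaN = event
        absent) and the level columns named by the regressor sets.
    covariates : dict
        Full-session continuous channels (length ``n_frames``).
    window_s : (float, float)
        Trial window relative to stimulus onset; windows of successive
        trials must not overlap.
    """
    if regressor_sets is None:
        regressor_sets = default_regressor_sets()
    if len(trials) == 0:
        raise ValueError("empty trial table")

    onsets = trials["stimulus_onset"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("stimulus onsets must be strictly increasing")
    win_lo, win_hi = window_s
    win_frames = int(round((win_hi - win_lo) * frame_rate_hz))
    starts = np.round((onsets + win_lo) * frame_rate_hz).astype(int)
    if starts[0] < 0 or starts[-1] + win_frames > n_frames:
        raise ValueError("trial window exceeds the recording; shorten window_s")
    if np.any(np.diff(starts) < win_frames):
        raise ValueError("trial windows overlap; shorten window_s or lengthen the ITI")

    cols: list[np.ndarray] = []
    meta: list[tuple[str, object, float, str, str]] = []
    n_dropped = 0
    for rset in regressor_sets:
        sub = trials
        if rset.condition is not None:
            sub = sub[sub[rset.condition].astype(bool)]
        if rset.kind == "event":
            if rset.level_by is None:
                level_groups = [("", sub)]
            else:
                # derived levels without any event (e.g. the "miss"
                # choice value, whose lick times are all NaN) are not
                # levels of the regressor and are dropped
                level_groups = [
                    (lv, g) for lv, g in sub.groupby(rset.level_by, sort=True)
                    if np.isfinite(g[rset.align].to_numpy(dtype=float)).any()
                ]
            for level, group in level_groups:
                times = group[rset.align].to_numpy(dtype=float)
                times = times[np.isfinite(times)]
                in_range = (times >= 0) & (times <= n_frames / frame_rate_hz)
                n_dropped += int((~in_range).sum())
                times = times[in_range]
                for k in rset.offsets:
                    col = np.zeros(n_frames)
                    _render_events(col, times, float(k), frame_rate_hz, n_frames)
                    cols.append(col)
                    meta.append((rset.label, level, float(k), rset.subgroup, rset.epoch))
        elif rset.kind == "continuous":
            chan = np.asarray(covariates[rset.align], dtype=float)
            if len(chan) != n_frames:
                raise ValueError(f"covariate {rset.align!r} length mismatch")
            smoothed = smooth_trace(chan, frame_rate_hz)
            for k in rset.offsets:
                cols.append(_shift_trace(smoothed, float(k), frame_rate_hz))
                meta.append((rset.label, "", float(k), rset.subgroup, rset.epoch))
        else:
            raise ValueError(f"unknown regressor kind {rset.kind!r}")

    if n_dropped:
        warnings.warn(f"{n_dropped} events outside the recording were dropped",
                      stacklevel=2)
    cols.append(np.ones(n_frames))
    meta.append(("offset", "", 0.0, "offset", "offset"))

    X = np.column_stack(cols)
    columns = pd.DataFrame(
        meta, columns=["set_label", "level", "offset_s", "subgroup", "epoch"])
    return DesignMatrix(
        X=X,
        columns=columns,
        frame_rate_hz=frame_rate_hz,
        trial_starts=starts,
        frames_per_trial=win_frames,
        trial_index=trials.reset_index(drop=True),
    )
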