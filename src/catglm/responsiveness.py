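"""Responsive fractions, their clustering, and learning-dynamics models.

A neuron counts as responsive to a stimulus when, across that
stimulus' trials, (1) a Mann-Whitney U test finds the mean inferred
spike rate in the second after stimulus onset significantly different
from the second before (P < 0.05) and (2) the peak of the
trial-averaged post-onset trace exceeds the pre-onset mean rate by at
least 0.01 (per second by default). Because the chance of detecting
responsiveness grows with trial count, in-task sessions are subsampled
to eight trials per stimulus, 100 times, yielding a per-neuron
responsiveness *probability*; out-of-task tuning-curve sessions (eight
repeats per stimulus by design) yield a binary outcome. The mean of
these probabilities is the session's trial-count-corrected fraction of
responsive neurons.

Across a chronic series of sessions the time-varying fractions are
clustered by k-means (cluster count chosen where real inertia beats
shuffled inertia the most) and decomposed into four interpretable
components: a stable baseline, an exponentially decaying fraction
(long-term adaptation), an in-task increase (task engagement) and a
post-learning increase (recruitment by learning).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _nnls
from sklearn.cluster import KMeans

from .exact_stats import mann_whitney_u_exact
from .session import SessionRecording

__all__ = [
    "stimulus_responsiveness_test",
    "responsive_probability",
    "fraction_responsive",
    "ClusterSolution",
    "cluster_time_patterns",
    "ComponentModelFit",
    "fit_component_model",
    "TIME_POINT_LABELS",
]

#: session time-point vocabulary of a chronic recording
TIME_POINT_LABELS = ("TC1", "TC2", "task_bs", "task_bs2", "task_learned", "TC_final")
IN_TASK_LABELS = ("task_bs", "task_bs2", "task_learned")
POST_LEARNING_LABELS = ("task_learned", "TC_final")


def _stimulus_trials(trials: pd.DataFrame, stimulus) -> np.ndarray:
    ori, sf, direction = stimulus
    mask = ((trials["ori_index"] == ori) & (trials["sf_index"] == sf)
            & (trials["direction"] == direction))
    return np.flatnonzero(mask.to_numpy())


def _window_rates(session: SessionRecording, neuron: int, trial_rows: np.ndarray,
                  window_s: float = 1.0):
    """Per-trial mean pre/post rates and the trial-averaged post trace (1/s)."""
    fr = session.frame_rate_hz
    w = int(round(window_s * fr))
    onsets = session.trials["stimulus_onset"].to_numpy(dtype=float)[trial_rows]
    onset_frames = np.round(onsets * fr).astype(int)
    if np.any(onset_frames - w < 0) or np.any(onset_frames + w > session.n_frames):
        raise ValueError("pre/post windows exceed the recording")
    trace = session.activity[neuron] * fr  # spikes/frame -> spikes/s
    pre_idx = onset_frames[:, None] + np.arange(-w, 0)[None, :]
    post_idx = onset_frames[:, None] + np.arange(0, w)[None, :]
    pre = trace[pre_idx]
    post = trace[post_idx]
    return pre.mean(axis=1), post.mean(axis=1), post.mean(axis=0)


def stimulus_responsiveness_test(session: SessionRecording, neuron: int, stimulus,
                                 trial_subset=None, alpha: float = 0.05,
                                 peak_threshold: float = 0.01,
                                 rate_units: str = "per_second") -> bool:
    """Joint significance + effect-size responsiveness criterion.

    ``stimulus`` is an ``(ori_index, sf_index, direction)`` triple;
    ``trial_subset`` restricts to those rows of the trial table.
    ``rate_units`` sets the units in which the 0.01 peak-difference
    threshold is applied ("per_second" or "per_frame").
    """
    rows = _stimulus_trials(session.trials, stimulus)
    if trial_subset is not None:
        rows = np.intersect1d(rows, np.asarray(trial_subset))
    if len(rows) < 2:
        raise ValueError("need at least 2 trials of the stimulus")
    pre, post, post_trace = _window_rates(session, neuron, rows)
    scale = 1.0 if rate_units == "per_second" else 1.0 / session.frame_rate_hz
    peak_diff = (post_trace.max() - pre.mean()) * scale
    if peak_diff < peak_threshold:
        return False
    result = mann_whitney_u_exact(post, pre, sidedness="two")
    return bool(result.p_value < alpha)


def responsive_probability(session: SessionRecording, neuron: int, stimuli=None,
                           n_subsample: int = 8, n_repeats: int = 100,
                           seed=None, in_task: bool = True, **test_kwargs) -> float:
    """Trial-count-corrected probability of responding to >= 1 stimulus.

    In-task: for each of ``n_repeats`` rounds, ``n_subsample`` trials
    are drawn without replacement per stimulus and the responsiveness
    criterion applied; the probability is the fraction of rounds with
    at least one significant stimulus. Out-of-task (``in_task=False``):
    all trials are used once, returning 0.0 or 1.0.
    """
    trials = session.trials
    if stimuli is None:
        stimuli = [tuple(v) for v in
                   trials[["ori_index", "sf_index", "direction"]]
                   .drop_duplicates().to_numpy()]
    per_stim_rows = {s: _stimulus_trials(trials, s) for s in stimuli}
    if not in_task:
        return float(any(
            stimulus_responsiveness_test(session, neuron, s, **test_kwargs)
            for s in stimuli
        ))
    deficient = [s for s, rows in per_stim_rows.items() if len(rows) < n_subsample]
    if deficient:
        raise ValueError(f"stimuli with fewer than {n_subsample} trials: {deficient}")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_repeats):
        for s, rows in per_stim_rows.items():
            subset = rng.choice(rows, size=n_subsample, replace=False)
            if stimulus_responsiveness_test(session, neuron, s,
                                            trial_subset=subset, **test_kwargs):
                hits += 1
                break
    return hits / n_repeats


def fraction_responsive(session: SessionRecording, neurons=None, **kwargs) -> float:
    """Session fraction of responsive neurons = mean per-neuron probability."""
    if neurons is None:
        neurons = range(session.n_neurons)
    probs = [responsive_probability(session, n, **kwargs) for n in neurons]
    return float(np.mean(probs))


# ---------------------------------------------------------------------------
# clustering of time-varying patterns


@dataclass
class ClusterSolution:
    """k-means solution plus its shuffled-inertia reference."""

    k: int
    assignments: np.ndarray
    inertia: float
    shuffled_inertia: float

    @property
    def delta_inertia(self) -> float:
        return self.shuffled_inertia - self.inertia


def _minmax_rows(patterns: np.ndarray) -> np.ndarray:
    lo = patterns.min(axis=1, keepdims=True)
    hi = patterns.max(axis=1, keepdims=True)
    span = hi - lo
    flat = (span == 0).ravel()
    out = np.empty_like(patterns, dtype=float)
    out[~flat] = (patterns[~flat] - lo[~flat]) / span[~flat]
    out[flat] = 0.5  # constant patterns carry no shape information
    return out


def cluster_time_patterns(patterns, k_range=range(2, 9), n_shuffles: int = 100,
                          n_init: int = 20, seed=None,
                          normalize: bool = True) -> dict[int, ClusterSolution]:
    """k-means over time-varying patterns with a shuffled-inertia null.

    Each pattern (row) is min-max normalized to [0, 1]; for every k the
    within-cluster sum of squares of the real data is compared to the
    mean inertia of ``n_shuffles`` datasets in which each pattern's
    values are independently permuted across time points. The best k
    maximizes delta inertia = shuffled - real; the returned dict of
    solutions carries ``selected_k`` in its ``attrs``-like entry via
    :func:`select_k`.
    """
    X = np.asarray(patterns, dtype=float)
    if X.ndim != 2:
        raise ValueError("patterns must be a 2D (recordings x time points) array")
    if np.isnan(X).any():
        raise ValueError("patterns contain missing values; align by label first")
    if normalize:
        X = _minmax_rows(X)
    k_range = [k for k in k_range]
    if X.shape[0] < max(k_range):
        raise ValueError("fewer recordings than the largest requested k")
    rng = np.random.default_rng(seed)

    shuffles = np.empty((n_shuffles,) + X.shape)
    for s in range(n_shuffles):
        for i in range(X.shape[0]):
            shuffles[s, i] = X[i, rng.permutation(X.shape[1])]

    out: dict[int, ClusterSolution] = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_init,
                    random_state=int(rng.integers(2**31)))
        km.fit(X)
        shuf_inertia = np.mean([
            KMeans(n_clusters=k, n_init=n_init,
                   random_state=int(rng.integers(2**31))).fit(shuffles[s]).inertia_
            for s in range(n_shuffles)
        ])
        out[k] = ClusterSolution(k=k, assignments=km.labels_.copy(),
                                 inertia=float(km.inertia_),
                                 shuffled_inertia=float(shuf_inertia))
    return out


def select_k(solutions: dict[int, ClusterSolution]) -> int:
    """The k maximizing delta inertia (shuffled minus real)."""
    return max(solutions.values(), key=lambda s: s.delta_inertia).k


# ---------------------------------------------------------------------------
# four-component model of learning dynamics


@dataclass
class ComponentModelFit:
    """Nonnegative decomposition of a responsive-fraction time course."""

    weights: dict[str, float]
    r2: float
    delta_r2: dict[str, float] = field(default_factory=dict)
    zero_variance: bool = False
    rank_deficient: bool = False
    residuals: np.ndarray = field(default=None, repr=False)

    COMPONENTS = ("base", "decay", "task", "learning")


def component_design(time_point_labels) -> np.ndarray:
    """Columns: base (1), decay (2^-index), task and learning indicators."""
    labels = list(time_point_labels)
    n = len(labels)
    base = np.ones(n)
    decay = 2.0 ** -np.arange(n, dtype=float)
    task = np.array([lab in IN_TASK_LABELS for lab in labels], dtype=float)
    learning = np.array([lab in POST_LEARNING_LABELS for lab in labels], dtype=float)
    return np.column_stack([base, decay, task, learning])


def fit_component_model(pattern, time_point_labels, n_shuffles: int = 100,
                        seed=None) -> ComponentModelFit:
    """NNLS fit of the four learning-dynamics components to one pattern.

    delta R^2 per shuffleable component (decay, task, learning) is the
    full-model R^2 minus the mean R^2 over ``n_shuffles`` refits with
    that component's values permuted across time points; base is the
    intercept and cannot be shuffled.
    """
    y = np.asarray(pattern, dtype=float)
    labels = list(time_point_labels)
    if len(y) != len(labels):
        raise ValueError("pattern and time_point_labels must be aligned")
    if len(y) < 4:
        raise ValueError("need at least 4 time points")
    unknown = [lab for lab in labels if lab not in TIME_POINT_LABELS]
    if unknown:
        raise ValueError(f"unknown time-point labels: {unknown}")

    D = component_design(labels)
    rank_deficient = np.linalg.matrix_rank(D) < D.shape[1]
    if rank_deficient:
        warnings.warn("component design is rank deficient for these labels; "
                      "weights are a pseudo-solution", stacklevel=2)

    def _fit(Dm):
        w, _ = _nnls(Dm, y)
        pred = Dm @ w
        ss_res = float(np.sum((pred - y) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        return w, pred, ss_res, ss_tot

    w, pred, ss_res, ss_tot = _fit(D)
    zero_variance = ss_tot == 0.0
    r2 = 1.0 if zero_variance else 1.0 - ss_res / ss_tot

    rng = np.random.default_rng(seed)
    delta: dict[str, float] = {}
    if not zero_variance:
        for ci, name in enumerate(ComponentModelFit.COMPONENTS):
            if name == "base":
                continue
            r2s = np.empty(n_shuffles)
            for s in range(n_shuffles):
                Dm = D.copy()
                Dm[:, ci] = D[rng.permutation(len(y)), ci]
                _, _, sres, stot = _fit(Dm)
                r2s[s] = 1.0 - sres / stot
            delta[name] = float(r2 - r2s.mean())

    weights = dict(zip(ComponentModelFit.COMPONENTS, (float(v) for v in w)))
    return ComponentModelFit(weights=weights, r2=float(r2), delta_r2=delta,
                             zero_variance=zero_variance,
                             rank_deficient=rank_deficient, residuals=y - pred)
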