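"""Single-neuron encoding model: NNLS + L1 fits and their diagnostics.

The model predicts a neuron's smoothed inferred-spike trace from the
design matrix of :mod:`catglm.design` with nonnegative weights and an
L1 penalty:

    minimize  ||y - X w||^2 + lambda * sum(w)   subject to  w >= 0

Because the penalty is linear on the nonnegative orthant this is
exactly a nonnegative quadratic program,

    minimize  w' (X'X) w - 2 (X'y - lambda/2 * 1)' w,   w >= 0,

which is solved through a Cholesky refactorization and the
Lawson-Hanson active-set algorithm. Model quality is the
cross-validated R^2 = 1 - SS_residual / SS_total over held-out trials
(trial-level 70/30 splits, repeated). Significance compares the
cross-validated R^2 distribution against fits of a trial-identity
shuffled response using two bootstrap confidence-interval conditions;
unique subgroup contributions (delta R^2) shuffle only the columns of
one regressor subgroup across trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cholesky
from scipy.optimize import nnls as _lawson_hanson_nnls

from .design import DesignMatrix, RegressorSet, build_design_matrix, smooth_trace
from .exact_stats import bootstrap_mean_ci
from .session import SessionRecording

__all__ = [
    "GlmFit",
    "GlmEngine",
    "fit_nnls_l1",
    "cross_validated_fit",
    "significance_by_shuffle",
    "subgroup_delta_r2",
    "classify_modulation_change",
    "max_vif",
]

#: how the L1 penalty scales with the response: "response_sum" sets
#: lambda = l1_scale * sum(y_train) (scale equivariant, the default);
#: "n_samples" sets lambda = l1_scale * len(y_train).
L1_SIZE_MODES = ("response_sum", "n_samples")


def _solve_nnls_qp(G: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimize w'Gw - 2b'w subject to w >= 0 (G PSD).

    Refactors the quadratic as an ordinary NNLS problem through a
    jittered Cholesky factor and solves it with Lawson-Hanson.
    """
    n = G.shape[0]
    eps = 1e-10 * (np.trace(G) / n + 1.0)
    L = cholesky(G + eps * np.eye(n), lower=False)  # G ~ L'L
    c = np.linalg.solve(L.T, b)
    w, _ = _lawson_hanson_nnls(L, c)
    return w


def fit_nnls_l1(design, response, l1_scale: float = 0.01,
                l1_size: str = "response_sum") -> np.ndarray:
    """Nonnegative least squares with a linear L1 penalty.

    ``design`` may be a plain (n_samples, n_columns) matrix or a
    :class:`DesignMatrix` (then only included frames are used).
    ``lambda = l1_scale * size`` where ``size`` is the response sum
    (default) or the sample count, per ``l1_size``.
    """
    if isinstance(design, DesignMatrix):
        idx = design.included_frames()
        X = design.X[idx]
        y = np.asarray(response, dtype=float)[idx]
    else:
        X = np.asarray(design, dtype=float)
        y = np.asarray(response, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("design and response must be finite")
    if X.shape[0] != len(y):
        raise ValueError("response length must match design rows")
    lam = _l1_lambda(y, l1_scale, l1_size)
    G = X.T @ X
    b = X.T @ y - lam / 2.0
    return _solve_nnls_qp(G, b)


def _l1_lambda(y_train: np.ndarray, l1_scale: float, l1_size: str) -> float:
    if l1_size == "response_sum":
        return l1_scale * float(np.sum(y_train))
    if l1_size == "n_samples":
        return l1_scale * float(len(y_train))
    raise ValueError(f"l1_size must be one of {L1_SIZE_MODES}")


def _r_squared(y: np.ndarray, pred: np.ndarray) -> float:
    """R^2 = 1 - SS_residual / SS_total with the mean of ``y`` itself."""
    ss_res = float(np.sum((pred - y) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else -np.inf
    return 1.0 - ss_res / ss_tot


@dataclass
class GlmFit:
    """Result of repeated cross-validated NNLS + L1 fits for one neuron."""

    weights: np.ndarray = field(repr=False)     # n_repeats x n_columns
    train_r2: np.ndarray = field(repr=False)
    test_r2: np.ndarray = field(repr=False)
    columns: pd.DataFrame = field(repr=False)
    neuron: int | None = None
    l1_scale: float = 0.01
    label: str = ""

    @property
    def n_repeats(self) -> int:
        return len(self.test_r2)

    @property
    def mean_test_r2(self) -> float:
        return float(np.mean(self.test_r2))

    @property
    def mean_weights(self) -> np.ndarray:
        """Weights averaged across cross-validation repeats."""
        return self.weights.mean(axis=0)

    def set_mean_weight(self, set_label: str, level=None) -> float:
        """Mean (over repeats and offsets) weight of one regressor set."""
        meta = self.columns
        mask = meta["set_label"].to_numpy() == set_label
        if level is not None:
            mask &= meta["level"].astype(str).to_numpy() == str(level)
        if not mask.any():
            raise ValueError(f"no columns for set {set_label!r} level {level!r}")
        return float(self.mean_weights[mask].mean())


class GlmEngine:
    """Shared per-session state for fast repeated GLM fits.

    Precomputes the trial tensor and per-trial Gram matrices of the
    design so that every cross-validation split costs a Gram sum and
    one active-set solve rather than a full matrix product. All
    randomness flows through explicit seeds.
    """

    def __init__(self, session: SessionRecording,
                 regressor_sets: list[RegressorSet] | None = None,
                 window_s: tuple[float, float] = (-1.5, 5.5),
                 smooth_response: bool = True,
                 l1_scale: float = 0.01, l1_size: str = "response_sum"):
        self.session = session
        self.design = build_design_matrix(
            session.trials, session.covariates, session.n_frames,
            session.frame_rate_hz, regressor_sets=regressor_sets,
            window_s=window_s,
        )
        self.smooth_response = smooth_response
        self.l1_scale = l1_scale
        self.l1_size = l1_size
        self.Xt = self.design.trial_tensor()            # T x F x C
        self.grams = np.einsum("tfc,tfd->tcd", self.Xt, self.Xt)

    # -- responses ---------------------------------------------------------

    def response_windows(self, neuron: int) -> np.ndarray:
        """(n_trials, frames_per_trial) smoothed response of one neuron."""
        trace = self.session.activity[neuron]
        if self.smooth_response:
            trace = smooth_trace(trace, self.session.frame_rate_hz)
        return self.design.slice_response(trace)

    # -- fitting -----------------------------------------------------------

    def _fit_split(self, Y: np.ndarray, train: np.ndarray, test: np.ndarray,
                   bt: np.ndarray) -> tuple[np.ndarray, float, float]:
        G = self.grams[train].sum(axis=0)
        y_train = Y[train].ravel()
        lam = _l1_lambda(y_train, self.l1_scale, self.l1_size)
        b = bt[train].sum(axis=0) - lam / 2.0
        w = _solve_nnls_qp(G, b)
        pred_train = np.einsum("tfc,c->tf", self.Xt[train], w).ravel()
        pred_test = np.einsum("tfc,c->tf", self.Xt[test], w).ravel()
        return w, _r_squared(y_train, pred_train), _r_squared(Y[test].ravel(), pred_test)

    def cross_validated_fit(self, neuron: int, n_repeats: int = 100,
                            train_fraction: float = 0.7, seed=None,
                            shuffle_trials: bool = False,
                            shuffle_subgroup: str | None = None,
                            label: str = "") -> GlmFit:
        """Repeated trial-level 70/30 fits; optionally on shuffled data.

        ``shuffle_trials`` permutes the assignment of per-trial response
        windows to per-trial design windows (the trial-identity shuffle
        used for the significance null: within-trial temporal structure
        and offsets are preserved). ``shuffle_subgroup`` instead
        permutes only the design columns of one subgroup across trials
        (a fresh permutation per repeat), for unique-contribution
        delta R^2.
        """
        T = self.design.n_trials
        if T < 10:
            raise ValueError("need at least 10 trials for cross-validated fits")
        n_train = int(round(train_fraction * T))
        if n_train < 1 or n_train >= T:
            raise ValueError("train_fraction leaves an empty train or test set")
        rng = np.random.default_rng(seed)
        Y_base = self.response_windows(neuron)
        bt = None if shuffle_trials else np.einsum("tfc,tf->tc", self.Xt, Y_base)

        weights = np.empty((n_repeats, self.design.n_columns))
        train_r2 = np.empty(n_repeats)
        test_r2 = np.empty(n_repeats)
        for r in range(n_repeats):
            if shuffle_trials:
                # fresh trial-identity permutation per repeat, so the
                # shuffled R^2 distribution carries permutation variance
                Y = Y_base[rng.permutation(T)]
                bt_r = np.einsum("tfc,tf->tc", self.Xt, Y)
            else:
                Y, bt_r = Y_base, bt
            perm = rng.permutation(T)
            train, test = np.sort(perm[:n_train]), np.sort(perm[n_train:])
            if shuffle_subgroup is not None:
                w, tr, te = self._fit_split_subgroup_shuffled(
                    Y, train, test, shuffle_subgroup, rng)
            else:
                w, tr, te = self._fit_split(Y, train, test, bt_r)
            weights[r], train_r2[r], test_r2[r] = w, tr, te
        return GlmFit(weights=weights, train_r2=train_r2, test_r2=test_r2,
                      columns=self.design.columns, neuron=neuron,
                      l1_scale=self.l1_scale, label=label)

    def _fit_split_subgroup_shuffled(self, Y, train, test, subgroup: str,
                                     rng) -> tuple[np.ndarray, float, float]:
        """One split with the subgroup's columns trial-permuted.

        The shuffled design's Gram decomposes into the cached
        unshuffled block (other columns), the cached block of the
        permuted trials (subgroup columns) and a fresh cross block --
        only the cross block needs an explicit product.
        """
        S = self.design.subgroup_columns(subgroup)
        A = np.setdiff1d(np.arange(self.design.n_columns), S)
        T = self.design.n_trials
        perm = rng.permutation(T)
        n = self.design.n_columns

        G = np.empty((n, n))
        G[np.ix_(A, A)] = self.grams[np.ix_(train, A, A)].sum(axis=0)
        G[np.ix_(S, S)] = self.grams[np.ix_(perm[train], S, S)].sum(axis=0)
        cross = np.einsum("tfa,tfs->as",
                          self.Xt[np.ix_(train, np.arange(self.Xt.shape[1]), A)],
                          self.Xt[np.ix_(perm[train], np.arange(self.Xt.shape[1]), S)])
        G[np.ix_(A, S)] = cross
        G[np.ix_(S, A)] = cross.T

        y_train = Y[train].ravel()
        lam = _l1_lambda(y_train, self.l1_scale, self.l1_size)
        b = np.empty(n)
        b[A] = np.einsum("tfa,tf->a",
                         self.Xt[np.ix_(train, np.arange(self.Xt.shape[1]), A)],
                         Y[train])
        b[S] = np.einsum("tfs,tf->s",
                         self.Xt[np.ix_(perm[train], np.arange(self.Xt.shape[1]), S)],
                         Y[train])
        w = _solve_nnls_qp(G, b - lam / 2.0)

        def _predict(idx):
            return (np.einsum("tfa,a->tf", self.Xt[np.ix_(idx, np.arange(self.Xt.shape[1]), A)], w[A])
                    + np.einsum("tfs,s->tf", self.Xt[np.ix_(perm[idx], np.arange(self.Xt.shape[1]), S)], w[S]))

        pred_train = _predict(train).ravel()
        pred_test = _predict(test).ravel()
        return w, _r_squared(y_train, pred_train), _r_squared(Y[test].ravel(), pred_test)


def cross_validated_fit(session: SessionRecording, neuron: int,
                        regressor_sets: list[RegressorSet] | None = None,
                        n_repeats: int = 100, train_fraction: float = 0.7,
                        seed=None, engine: GlmEngine | None = None,
                        **engine_kwargs) -> GlmFit:
    """Convenience wrapper building a :class:`GlmEngine` per call.

    For many neurons of one session, build the engine once and call its
    method directly.
    """
    if engine is None:
        engine = GlmEngine(session, regressor_sets=regressor_sets, **engine_kwargs)
    return engine.cross_validated_fit(neuron, n_repeats=n_repeats,
                                      train_fraction=train_fraction, seed=seed)


def significance_by_shuffle(fit: GlmFit, shuffled_fit: GlmFit,
                            confidence: float = 0.95, n_resamples: int = 1000,
                            interval: str = "values", seed=None) -> bool:
    """Two-condition comparison of real vs shuffled R^2 distributions.

    True iff (1) the mean shuffled R^2 lies below the lower 95% bound
    of the unshuffled R^2 values AND (2) the mean unshuffled R^2 lies
    above the upper 95% bound of the shuffled R^2 values.

    With ``interval="values"`` (default) the bounds are the percentile
    interval of the R^2 *value* distribution across repeats, which
    carries both the split and the shuffle-permutation variance and
    calibrates near its nominal rate on pure-noise neurons.
    ``interval="mean_ci"`` instead uses the bootstrap confidence
    interval of the mean R^2; because cross-validation repeats of the
    same data are strongly dependent, that interval ignores the
    data-realization variance and flags far more than 5% of null
    neurons -- kept only for comparison.
    """
    alpha = (1.0 - confidence) / 2.0
    rng = np.random.default_rng(seed)
    if interval == "values":
        mean_real, lo_real = float(np.mean(fit.test_r2)), float(
            np.quantile(fit.test_r2, alpha))
        mean_shuf, hi_shuf = float(np.mean(shuffled_fit.test_r2)), float(
            np.quantile(shuffled_fit.test_r2, 1.0 - alpha))
    elif interval == "mean_ci":
        mean_real, lo_real, _ = bootstrap_mean_ci(
            fit.test_r2, n_resamples, confidence, seed=rng.integers(2**31))
        mean_shuf, _, hi_shuf = bootstrap_mean_ci(
            shuffled_fit.test_r2, n_resamples, confidence, seed=rng.integers(2**31))
    else:
        raise ValueError("interval must be 'values' or 'mean_ci'")
    return bool(mean_shuf < lo_real and mean_real > hi_shuf)


def subgroup_delta_r2(engine: GlmEngine, neuron: int, fit: GlmFit,
                      subgroup: str, n_repeats: int | None = None,
                      seed=None, return_distributions: bool = False):
    """Unique contribution of one regressor subgroup.

    delta R^2 = mean cross-validated R^2 of the full model minus the
    mean cross-validated R^2 with that subgroup's columns shuffled
    across trials. A subgroup only contributes uniquely if no
    combination of the remaining regressors can absorb its variance.
    """
    n_repeats = n_repeats or fit.n_repeats
    shuffled = engine.cross_validated_fit(
        neuron, n_repeats=n_repeats, seed=seed,
        shuffle_subgroup=subgroup, label=f"shuffled:{subgroup}")
    delta = fit.mean_test_r2 - shuffled.mean_test_r2
    if return_distributions:
        return delta, shuffled
    return delta


def classify_modulation_change(significant_baseline, significant_learned,
                               neuron_ids=None) -> pd.DataFrame:
    """Stable / gained / lost / never classes across learning.

    Inputs are aligned boolean sequences of GLM significance at the
    in-task baseline and post-learning time points for the same
    matched neurons. The attached ``changed_stable_ratio`` attribute
    is (gained + lost) / stable.
    """
    sig_b = np.asarray(significant_baseline, dtype=bool)
    sig_l = np.asarray(significant_learned, dtype=bool)
    if sig_b.shape != sig_l.shape:
        raise ValueError("baseline and learned significance must be aligned")
    if neuron_ids is None:
        neuron_ids = np.arange(len(sig_b))
    cls = np.where(sig_b & sig_l, "stable",
                   np.where(sig_l, "gained", np.where(sig_b, "lost", "never")))
    out = pd.DataFrame({"neuron": neuron_ids, "class": cls,
                        "significant_baseline": sig_b, "significant_learned": sig_l})
    n_stable = int((cls == "stable").sum())
    n_changed = int(((cls == "gained") | (cls == "lost")).sum())
    if n_stable == 0 and n_changed == 0:
        raise ValueError("no neuron significant at either time point; ratio undefined")
    out.attrs["changed_stable_ratio"] = (n_changed / n_stable if n_stable > 0
                                         else np.inf)
    return out


def max_vif(design: DesignMatrix, subgroups=("stimulus-task", "orientation",
                                             "spatial_frequency", "category",
                                             "choice", "reward-timeout"),
            mode: str = "across_epochs") -> tuple[float, dict]:
    """Maximum variance inflation factor over the named subgroups.

    For every kernel column of the named subgroups, VIF = 1/(1 - R^2)
    of an ordinary least-squares regression of that (centered) column
    on a pool of other columns over the included frames, maximized
    over columns. The predictor pool depends on ``mode``:

    across_epochs (default)
        All columns of regressor sets from *other trial epochs*
        (stimulus-locked vs response-locked vs locomotion). This asks
        the scientifically relevant question -- can stimulus, category,
        choice and reward kernels mimic each other across epochs? --
        and is the only pool on which the diagnostic is finite by
        construction: sets within one epoch share (near-)identical
        event times and are redundant by design (the decisive lick
        *is* the reward/time-out moment; every trial carries exactly
        one orientation, spatial frequency and category, and a linear
        staircase boundary makes the category indicator additively
        separable into orientation + spatial-frequency indicators).
    within_set
        The other time offsets of the same (set, level): measures
        over-completeness of the Gaussian basis at its 0.5-s spacing.
    across_sets
        All columns of other regressor sets (inherits the structural
        within-epoch infinities; diagnosis only).
    all
        Every other column (textbook definition; diagnosis only).

    A perfectly collinear column is reported as ``inf`` together with
    its identity. Returns ``(max_vif, per_column)`` where
    ``per_column`` maps ``(set_label, level, offset)`` to its VIF.
    """
    if mode not in ("across_epochs", "within_set", "across_sets", "all"):
        raise ValueError("mode must be 'across_epochs', 'within_set', "
                         "'across_sets' or 'all'")
    idx = design.included_frames()
    X = design.X[idx]
    meta = design.columns
    keep = meta["subgroup"].to_numpy() != "offset"
    Xc = X[:, keep] - X[:, keep].mean(axis=0, keepdims=True)
    meta = meta[keep].reset_index(drop=True)
    G = Xc.T @ Xc
    sst = np.diag(G).copy()

    targets = np.flatnonzero(meta["subgroup"].isin(subgroups).to_numpy())
    if len(targets) < 2:
        raise ValueError("need at least 2 columns in the named subgroups")
    set_labels = meta["set_label"].to_numpy()
    levels = meta["level"].astype(str).to_numpy()
    epochs = meta["epoch"].to_numpy()
    vifs: dict[tuple, float] = {}
    for j in targets:
        if sst[j] <= 0:
            continue  # constant column: no variance to inflate
        same_set = set_labels == set_labels[j]
        if mode == "across_epochs":
            others = np.flatnonzero(epochs != epochs[j])
        elif mode == "within_set":
            others = np.flatnonzero(same_set & (levels == levels[j]))
            others = others[others != j]
        elif mode == "across_sets":
            others = np.flatnonzero(~same_set)
        else:
            others = np.delete(np.arange(G.shape[0]), j)
        if len(others) == 0:
            continue
        Goo = G[np.ix_(others, others)]
        goj = G[others, j]
        coef, *_ = np.linalg.lstsq(Goo, goj, rcond=None)
        sse = sst[j] - goj @ coef
        r2 = 1.0 - max(sse, 0.0) / sst[j]
        key = (meta.at[j, "set_label"], meta.at[j, "level"], meta.at[j, "offset_s"])
        vifs[key] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return max(vifs.values()), vifs
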