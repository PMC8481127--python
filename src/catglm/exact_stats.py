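"""Exact small-sample rank tests and the bootstrap mean CI.

Group sizes in chronic-imaging experiments are small (often five to
fifteen animals or recordings), where asymptotic p-values of rank tests
are unreliable. The Wilcoxon matched-pairs signed-rank (WMPSR) test and
the Mann-Whitney U test here compute exact p-values by enumerating the
full permutation null whenever the sample is small enough, and fall
back to the tie-corrected normal approximation otherwise.

For example, five paired differences that all share one sign give
W = 15 (or 0) with a one-sided exact p of 1/32 ~ 0.031 -- the smallest
p-value attainable at n = 5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "wilcoxon_signed_rank_exact",
    "mann_whitney_u_exact",
    "bootstrap_mean_ci",
]

#: largest n for which the 2^n signed-rank null is enumerated
WILCOXON_EXACT_MAX_N = 25
#: largest n_a + n_b for which the Mann-Whitney null is enumerated
MANNWHITNEY_EXACT_MAX_N = 20


@dataclass
class TestResult:
    """Outcome of a nonparametric test."""

    statistic: float
    p_value: float
    n: int
    sidedness: str  # "one" or "two"
    method: str

    def __iter__(self):  # allow `stat, p = result`
        return iter((self.statistic, self.p_value))


def _check_sidedness(sidedness: str) -> str:
    if sidedness not in ("one", "two"):
        raise ValueError("sidedness must be 'one' or 'two'")
    return sidedness


def _signed_rank_null_counts(ranks: np.ndarray) -> np.ndarray:
    """Number of sign assignments reaching each positive-rank sum.

    Dynamic program over the 2**n equally likely sign vectors; with
    mid-ranks the attainable sums live on a half-unit lattice, handled
    by working in doubled units.
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled:
        counts[r:] = counts[r:] + counts[:-r or None]
    return counts


def wilcoxon_signed_rank_exact(paired_differences, sidedness: str = "two") -> TestResult:
    """Wilcoxon matched-pairs signed-rank test with an exact small-n null.

    Zero differences are dropped (Wilcoxon convention) and ties among
    the absolute differences receive mid-ranks. The statistic W is the
    sum of ranks of the positive differences; the one-sided p-value is
    P(W_null >= W). For n <= 25 the null is the exact enumeration of
    all 2**n sign assignments; beyond that, the tie-corrected normal
    approximation (with continuity correction) is used.
    """
    sidedness = _check_sidedness(sidedness)
    d = np.asarray(paired_differences, dtype=float)
    if d.ndim != 1:
        raise ValueError("paired_differences must be one-dimensional")
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero")

    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_total = float(ranks.sum())

    if n <= WILCOXON_EXACT_MAX_N:
        counts = _signed_rank_null_counts(ranks)
        idx = int(np.rint(2 * w_pos))
        p_ge = counts[idx:].sum() / 2.0**n
        p_le = counts[: idx + 1].sum() / 2.0**n
        method = "wilcoxon-signed-rank-exact"
    else:
        mu = w_total / 2.0
        # tie-corrected variance of W+ under random signs
        var = float(np.sum(ranks**2)) / 4.0
        sd = np.sqrt(var)
        p_ge = sps.norm.sf((w_pos - mu - 0.5) / sd)
        p_le = sps.norm.cdf((w_pos - mu + 0.5) / sd)
        method = "wilcoxon-signed-rank-normal"

    one_sided = min(p_ge, p_le)
    p = one_sided if sidedness == "one" else min(1.0, 2.0 * one_sided)
    return TestResult(w_pos, float(min(p, 1.0)), n, sidedness, method)


def mann_whitney_u_exact(sample_a, sample_b, sidedness: str = "two") -> TestResult:
    """Mann-Whitney U test with exact enumeration for small samples.

    U counts, over all cross-pairs, how often an observation from
    ``sample_a`` exceeds one from ``sample_b`` (ties count one half).
    For n_a + n_b <= 20 without ties the p-value comes from the exact
    distribution over all C(n_a + n_b, n_a) rank arrangements;
    otherwise the mid-rank, tie-corrected normal approximation is used.
    """
    sidedness = _check_sidedness(sidedness)
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    n_a, n_b = len(a), len(b)

    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r_a = float(ranks[:n_a].sum())
    u_a = r_a - n_a * (n_a + 1) / 2.0
    has_ties = len(np.unique(pooled)) < len(pooled)

    if n_a + n_b <= MANNWHITNEY_EXACT_MAX_N and not has_ties:
        counts = _mwu_exact_counts(n_a, n_b)
        total = counts.sum()
        idx = int(np.rint(u_a))
        p_ge = counts[idx:].sum() / total
        p_le = counts[: idx + 1].sum() / total
        method = "mann-whitney-u-exact"
    else:
        mu = n_a * n_b / 2.0
        n = n_a + n_b
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
        var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
        if var <= 0:  # all values identical
            return TestResult(u_a, 1.0, n_a + n_b, sidedness, "mann-whitney-u-degenerate")
        sd = np.sqrt(var)
        p_ge = sps.norm.sf((u_a - mu - 0.5) / sd)
        p_le = sps.norm.cdf((u_a - mu + 0.5) / sd)
        method = "mann-whitney-u-normal"

    one_sided = min(p_ge, p_le)
    p = one_sided if sidedness == "one" else min(1.0, 2.0 * one_sided)
    return TestResult(u_a, float(min(p, 1.0)), n_a + n_b, sidedness, method)


_MWU_COUNT_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _mwu_exact_counts(n_a: int, n_b: int) -> np.ndarray:
    """Exact null distribution of U as arrangement counts, no ties.

    Uses the classic recursion f(U; m, n) = f(U - n; m - 1, n) +
    f(U; m, n - 1), equivalent to enumerating every one of the
    C(m + n, m) rank arrangements.
    """
    key = (n_a, n_b)
    cached = _MWU_COUNT_CACHE.get(key)
    if cached is not None:
        return cached
    # f[m][n] is the count array over U = 0 .. m*n
    f: list[list[np.ndarray]] = [
        [np.zeros(m * n + 1) for n in range(n_b + 1)] for m in range(n_a + 1)
    ]
    for n in range(n_b + 1):
        f[0][n][0] = 1.0
    for m in range(1, n_a + 1):
        f[m][0][0] = 1.0
        for n in range(1, n_b + 1):
            cur = f[m][n]
            prev_m, prev_n = f[m - 1][n], f[m][n - 1]
            for u in range(m * n + 1):
                v = prev_n[u] if u <= m * (n - 1) else 0.0
                if u >= n:
                    v += prev_m[u - n]
                cur[u] = v
    _MWU_COUNT_CACHE[key] = f[n_a][n_b]
    return f[n_a][n_b]


def bootstrap_mean_ci(values, n_resamples: int = 1000, confidence: float = 0.95,
                      seed=None) -> tuple[float, float, float]:
    """Percentile bootstrap mean and confidence interval.

    Returns ``(mean, lower, upper)`` from ``n_resamples``
    with-replacement resamples of ``values``.
    """
    x = np.asarray(values, dtype=float).ravel()
    if len(x) < 2:
        raise ValueError("need at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(x), size=(n_resamples, len(x)))
    means = x[idx].mean(axis=1)
    alpha = (1.0 - confidence) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(x.mean()), float(lo), float(hi)
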