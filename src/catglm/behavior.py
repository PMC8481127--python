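"""Psychometric and boundary analyses of categorization behavior.

Trial tables are pandas DataFrames with one row per trial and at least
the columns ``ori_index``, ``sf_index``, ``category`` ("left"/"right"),
``choice`` ("left"/"right"/"miss"), ``response_made`` (bool),
``correct`` (bool; undefined on misses) and ``signed_distance`` (grid
units to the trained boundary). :func:`catglm.simulate.simulate_behavior_session`
produces tables in this layout; external CSVs with the same columns
work equally.

The behaviorally expressed category boundary is estimated either by
fitting a plane to the per-stimulus choice fractions and intersecting
it with z = 0.5 (dense spaces), or by a linear maximum-margin
separator on per-stimulus majority choices (reduced spaces with few
stimuli). Boundary angles follow the grid convention of
:mod:`catglm.spaces`: 0 deg = pure orientation rule, counter-clockwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn import svm

from .spaces import CategorySpace

__all__ = [
    "BoundaryFit",
    "SigmoidFit",
    "fraction_correct",
    "choice_fraction_by_distance",
    "fit_choice_sigmoid",
    "fit_expressed_boundary",
    "boundary_angle_diff",
]


@dataclass
class BoundaryFit:
    """A behaviorally expressed category boundary in grid units."""

    angle_deg: float          # in [0, 180)
    offset: float             # grid units along the boundary normal, from grid center
    method: str               # "plane" or "max_margin"
    goodness: float           # fraction of per-stimulus majority choices on the correct side


@dataclass
class SigmoidFit:
    """Four-parameter logistic fit of choice fraction vs boundary distance.

    y = floor + span / (1 + exp(-steepness * (x - midpoint)))
    """

    floor: float
    span: float
    midpoint: float
    steepness: float
    rss: float
    degenerate: bool = False

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return self.floor + self.span / (1.0 + np.exp(-self.steepness * (x - self.midpoint)))


def _responded(trials: pd.DataFrame) -> pd.DataFrame:
    return trials[trials["response_made"].astype(bool)]


def fraction_correct(trials: pd.DataFrame) -> float:
    """Fraction of correct trials among trials with a response.

    Miss trials enter neither numerator nor denominator.
    """
    resp = _responded(trials)
    if len(resp) == 0:
        raise ValueError("no responded trials: fraction correct undefined")
    return float(resp["correct"].astype(bool).mean())


def choice_fraction_by_distance(trials: pd.DataFrame,
                                boundary: BoundaryFit | None = None,
                                space: CategorySpace | None = None) -> pd.DataFrame:
    """Fraction of 'right' choices per distinct boundary distance.

    With ``boundary`` (and ``space`` for the grid center) given, the
    signed distance of each trial's stimulus to that fitted boundary is
    used; otherwise the table's ``signed_distance`` to the trained
    boundary. Returns a DataFrame with columns ``distance``,
    ``fraction_right`` and ``n_trials``, one row per distinct distance,
    sorted ascending. Misses are excluded.
    """
    resp = _responded(trials).copy()
    if boundary is not None:
        if space is None:
            raise ValueError("space is required to evaluate distances to a fitted boundary")
        a = np.deg2rad(boundary.angle_deg)
        cx, cy = space.grid_center
        resp["signed_distance"] = (
            np.cos(a) * (resp["ori_index"] - cx)
            + np.sin(a) * (resp["sf_index"] - cy)
            - boundary.offset
        )
    key = resp["signed_distance"].round(9)
    grouped = resp.groupby(key)
    out = pd.DataFrame(
        {
            "distance": grouped["signed_distance"].first(),
            "fraction_right": grouped["choice"].apply(lambda c: float((c == "right").mean())),
            "n_trials": grouped.size(),
        }
    ).sort_values("distance").reset_index(drop=True)
    return out


def _logistic4(x, floor, span, midpoint, steepness):
    return floor + span / (1.0 + np.exp(-steepness * (x - midpoint)))


def fit_choice_sigmoid(distance_table: pd.DataFrame, span_floor: float = 0.05) -> SigmoidFit:
    """Weighted least-squares 4-parameter logistic over a distance table.

    Rows are weighted by their trial counts. If the fitted span is
    below ``span_floor`` the steepness is unidentifiable and the fit is
    flagged degenerate.
    """
    x = distance_table["distance"].to_numpy(dtype=float)
    y = distance_table["fraction_right"].to_numpy(dtype=float)
    n = distance_table["n_trials"].to_numpy(dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 distinct distances for a sigmoid fit")

    span0 = max(y.max() - y.min(), 1e-3)
    p0 = [max(y.min(), 0.0), span0, float(np.median(x)), 1.0]
    bounds = ([0.0, 0.0, x.min() - np.ptp(x) - 1.0, 1e-6],
              [1.0, 1.0, x.max() + np.ptp(x) + 1.0, 1e6])
    sigma = 1.0 / np.sqrt(np.maximum(n, 1.0))
    try:
        popt, _ = curve_fit(_logistic4, x, y, p0=p0, sigma=sigma,
                            bounds=bounds, maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(f"sigmoid fit did not converge (start {p0})") from err
    floor, span, midpoint, steepness = (float(v) for v in popt)
    rss = float(np.sum(n * (y - _logistic4(x, *popt)) ** 2))
    return SigmoidFit(floor, span, midpoint, steepness, rss,
                      degenerate=span < span_floor)


def _per_stimulus_choices(trials: pd.DataFrame) -> pd.DataFrame:
    resp = _responded(trials)
    grouped = resp.groupby(["ori_index", "sf_index"])
    tab = pd.DataFrame(
        {
            "fraction_right": grouped["choice"].apply(lambda c: float((c == "right").mean())),
            "n_trials": grouped.size(),
        }
    ).reset_index()
    return tab


def fit_expressed_boundary(trials: pd.DataFrame, space: CategorySpace,
                           method: str = "plane") -> BoundaryFit:
    """Estimate the behaviorally expressed category boundary.

    plane
        Ordinary least squares of the per-stimulus fraction of "right"
        choices z on grid coordinates, z = a*ori + b*sf + c; the
        boundary is the locus z = 0.5 and the angle comes from the
        plane gradient (a, b).
    max_margin
        Linear maximum-margin separator (hard-margin SVM) on grid
        coordinates with per-stimulus majority-choice labels, samples
        weighted by trial counts; ties are excluded. Suited to reduced
        spaces with few distinct stimuli.
    """
    tab = _per_stimulus_choices(trials)
    cx, cy = space.grid_center
    x = tab["ori_index"].to_numpy(dtype=float) - cx
    y = tab["sf_index"].to_numpy(dtype=float) - cy

    if method == "plane":
        z = tab["fraction_right"].to_numpy(dtype=float)
        w = tab["n_trials"].to_numpy(dtype=float)
        if len(tab) < 3:
            raise ValueError("plane fit needs at least 3 distinct stimuli")
        design = np.column_stack([x, y, np.ones_like(x)])
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], z * sw, rcond=None)
        a, b, c = coef
        norm = float(np.hypot(a, b))
        if norm < 1e-12:
            raise ValueError("degenerate plane: no choice gradient across the grid")
        angle = float(np.degrees(np.arctan2(b, a))) % 180.0
        # signed offset of the z = 0.5 locus from the grid center, along
        # the normal pointing toward increasing fraction-right
        offset = float((0.5 - c) / norm)
    elif method == "max_margin":
        maj = np.where(tab["fraction_right"] > 0.5, "right",
                       np.where(tab["fraction_right"] < 0.5, "left", "tie"))
        keep = maj != "tie"
        labels = (maj[keep] == "right").astype(int)
        if labels.min() == labels.max():
            raise ValueError("all stimuli carry one majority label; no separator exists")
        clf = svm.SVC(kernel="linear", C=1e6)
        clf.fit(np.column_stack([x[keep], y[keep]]), labels,
                sample_weight=tab["n_trials"].to_numpy(dtype=float)[keep])
        wx, wy = clf.coef_[0]
        norm = float(np.hypot(wx, wy))
        if norm < 1e-12:
            raise ValueError("degenerate separator")
        angle = float(np.degrees(np.arctan2(wy, wx))) % 180.0
        offset = float(-clf.intercept_[0] / norm)
    else:
        raise ValueError(f"unknown boundary method: {method!r}")

    # goodness: per-stimulus majority choices falling on their side of the fit
    a_rad = np.deg2rad(angle)
    d = np.cos(a_rad) * x + np.sin(a_rad) * y - offset
    maj_right = tab["fraction_right"].to_numpy() > 0.5
    decided = tab["fraction_right"].to_numpy() != 0.5
    agree = (d > 0) == maj_right
    goodness = float(agree[decided].mean()) if decided.any() else float("nan")
    return BoundaryFit(angle_deg=angle, offset=offset, method=method, goodness=goodness)


def boundary_angle_diff(fit: BoundaryFit | float, trained_angle_deg: float) -> float:
    """Absolute angular difference between two boundaries, folded to [0, 90].

    Boundary orientations are axial (a line, not a ray), so the
    difference wraps at 180 deg and folds at 90 deg.
    """
    angle = fit.angle_deg if isinstance(fit, BoundaryFit) else float(fit)
    d = abs(angle - trained_angle_deg) % 180.0
    return float(min(d, 180.0 - d))
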