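"""Category tuning indices and choice selectivity from fitted GLM weights.

Neurons in visual cortex are feature tuned (orientation, spatial
frequency) long before category learning, so apparent category
selectivity can be a byproduct of feature tuning. Two indices
disentangle this, both computed from the encoding model's nonnegative
weights (means across cross-validation repeats and across the time
offsets within each regressor set):

* semantic CTI = (wL - wR) / (wL + wR), from the left/right *category*
  regressor sets: selectivity shared by all stimuli of a category,
  beyond what feature kernels explain.
* feature CTI aggregates each task stimulus' orientation and
  spatial-frequency weights by its category membership:
  (sum_left (w_ori + w_sf) - sum_right (...)) / (sum of both),
  capturing the category signal that feature tuning alone produces.

delta CTI = semantic - feature isolates genuine category tuning.
Choice selectivity applies the same contrast to the left/right choice
kernels. Weight nonnegativity bounds every index in [-1, 1]; a zero
denominator makes an index invalid and excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glm import GlmFit
from .spaces import CategorySpace

__all__ = [
    "CtiResult",
    "semantic_cti",
    "feature_cti",
    "delta_cti",
    "choice_selectivity",
    "cti_result",
]


@dataclass
class CtiResult:
    """Per-neuron category-tuning summary."""

    semantic: float
    feature: float
    choice: float
    semantic_valid: bool
    feature_valid: bool
    choice_valid: bool
    neuron: int | None = None

    @property
    def delta(self) -> float:
        """delta CTI = semantic - feature; NaN when either is invalid."""
        if not (self.semantic_valid and self.feature_valid):
            return float("nan")
        return self.semantic - self.feature


def _contrast(w_pos: float, w_neg: float) -> tuple[float, bool]:
    total = w_pos + w_neg
    if total <= 0:
        return float("nan"), False
    return (w_pos - w_neg) / total, True


def semantic_cti(fit: GlmFit) -> tuple[float, bool]:
    """(wL - wR)/(wL + wR) over the category regressor sets.

    Returns ``(index, valid)``; invalid when both mean category weights
    are zero.
    """
    w_l = fit.set_mean_weight("category", "left")
    w_r = fit.set_mean_weight("category", "right")
    return _contrast(w_l, w_r)


def feature_cti(fit: GlmFit, space: CategorySpace) -> tuple[float, bool]:
    """Category contrast of orientation + spatial-frequency weights.

    Every active task stimulus contributes the mean weight of its
    orientation level plus the mean weight of its spatial-frequency
    level, summed within its category.
    """
    sums = {"left": 0.0, "right": 0.0}
    for _, stim in space.active_stimuli().iterrows():
        w = (fit.set_mean_weight("orientation", stim["ori_index"])
             + fit.set_mean_weight("spatial_frequency", stim["sf_index"]))
        sums[stim["category"]] += w
    return _contrast(sums["left"], sums["right"])


def delta_cti(result: CtiResult) -> float:
    """semantic CTI minus feature CTI (NaN if either invalid)."""
    return result.delta


def choice_selectivity(fit: GlmFit, choice_sets=("choice_1", "choice_2"),
                       signed: bool = False) -> tuple[float, bool]:
    """Asymmetry of the fitted left/right choice kernels.

    ``|wL - wR| / (wL + wR)`` with weights averaged across repeats,
    offsets and the given choice regressor sets (both lick-sequence
    definitions by default). ``signed=True`` keeps the sign (positive =
    left-preferring).
    """
    w_l = float(np.mean([fit.set_mean_weight(s, "left") for s in choice_sets]))
    w_r = float(np.mean([fit.set_mean_weight(s, "right") for s in choice_sets]))
    value, valid = _contrast(w_l, w_r)
    if valid and not signed:
        value = abs(value)
    return value, valid


def cti_result(fit: GlmFit, space: CategorySpace, neuron: int | None = None,
               choice_sets=("choice_1", "choice_2"),
               negligible_fraction: float = 0.05) -> CtiResult:
    """Bundle semantic, feature and choice indices for one neuron.

    A ratio index computed from near-zero weights is dominated by
    fitting noise (a leak of <1% of a neuron's weight mass can swing
    the ratio to +-1), so an index whose denominator is below
    ``negligible_fraction`` of the neuron's combined category +
    feature weight mass is taken at its no-tuning limit of 0 (still
    flagged valid); only an exactly zero combined mass marks both
    indices invalid.
    """
    try:
        sem, sem_ok = semantic_cti(fit)
        denom_sem = (fit.set_mean_weight("category", "left")
                     + fit.set_mean_weight("category", "right"))
        cat_sets_present = True
    except ValueError:  # out-of-task model without category sets
        sem, sem_ok, denom_sem = float("nan"), False, 0.0
        cat_sets_present = False
    feat, feat_ok = feature_cti(fit, space)
    sums = {"left": 0.0, "right": 0.0}
    for _, stim in space.active_stimuli().iterrows():
        sums[stim["category"]] += (
            fit.set_mean_weight("orientation", stim["ori_index"])
            + fit.set_mean_weight("spatial_frequency", stim["sf_index"]))
    denom_feat = sums["left"] + sums["right"]
    total = denom_sem + denom_feat
    if total > 0:
        if cat_sets_present and denom_sem < negligible_fraction * total:
            sem, sem_ok = 0.0, True
        if denom_feat < negligible_fraction * total:
            feat, feat_ok = 0.0, True
    try:
        cho, cho_ok = choice_selectivity(fit, choice_sets)
    except ValueError:  # reduced (out-of-task) models without choice sets
        cho, cho_ok = float("nan"), False
    return CtiResult(semantic=sem, feature=feat, choice=cho,
                     semantic_valid=sem_ok, feature_valid=feat_ok,
                     choice_valid=cho_ok,
                     neuron=neuron if neuron is not None else fit.neuron)
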