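"""Fluorescence conditioning: neuropil correction and ratiometric dR/R.

Somatic fluorescence measured in vivo is contaminated by out-of-focus
neuropil signal and by slow common-mode intensity drift (for example
from z-drift of the imaging plane). The two steps here address both:

1. ``neuropil_correct`` subtracts a scaled (default 0.7) local neuropil
   trace from the ROI trace and restores the baseline by adding back
   the median of the scaled neuropil trace.
2. ``ratio_dff`` divides the activity channel (GCaMP) by a co-expressed
   structural channel (e.g. mRuby2), which cancels common-mode drift,
   and expresses the ratio R relative to a rolling baseline R0 taken
   from the lowest quartile of a 60-s window around each frame.
"""

from __future__ import annotations

import numpy as np

__all__ = ["neuropil_correct", "ratio_dff", "rolling_lower_quartile_baseline"]


def neuropil_correct(roi_trace, neuropil_trace, factor: float = 0.7) -> np.ndarray:
    """Subtract scaled neuropil signal, keeping the baseline level.

    ``out[t] = roi[t] - factor * np[t] + median(factor * np)``

    The median add-back offsets the overall reduction in baseline
    fluorescence so that downstream ratio baselines stay positive.
    """
    roi = np.asarray(roi_trace, dtype=float)
    npil = np.asarray(neuropil_trace, dtype=float)
    if roi.shape != npil.shape:
        raise ValueError("roi and neuropil traces must have equal length")
    scaled = factor * npil
    return roi - scaled + np.median(scaled)


def rolling_lower_quartile_baseline(trace, frame_rate_hz: float, window_s: float = 60.0,
                                    baseline_fraction: float = 0.25) -> np.ndarray:
    """Per-frame baseline: mean of the lowest-quartile values in a window.

    The window of ``window_s`` seconds is centered on each frame and
    truncated at the trace edges (no padding).
    """
    x = np.asarray(trace, dtype=float)
    n = len(x)
    half = max(1, int(round(window_s * frame_rate_hz / 2.0)))
    out = np.empty(n)

    # edges: truncated windows, computed individually
    edge = min(half, n)
    for i in list(range(edge)) + list(range(max(edge, n - half), n)):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        win = np.sort(x[lo:hi])
        k = max(1, int(np.ceil(baseline_fraction * len(win))))
        out[i] = win[:k].mean()

    # interior: full windows, vectorized in chunks to bound memory
    start, stop = edge, n - half
    if stop > start:
        w = 2 * half + 1
        k = max(1, int(np.ceil(baseline_fraction * w)))
        windows = np.lib.stride_tricks.sliding_window_view(x, w)
        for lo in range(start, stop, 4096):
            hi = min(stop, lo + 4096)
            block = np.partition(windows[lo - half : hi - half], k - 1, axis=1)
            out[lo:hi] = block[:, :k].mean(axis=1)
    return out


def ratio_dff(signal_trace, structural_trace, frame_rate_hz: float,
              window_s: float = 60.0, baseline_fraction: float = 0.25) -> np.ndarray:
    """Drift-resistant dR/R from a two-channel recording.

    R = signal / structural; R0 is the rolling lower-quartile baseline
    of R; the result is (R - R0) / R0. Because any multiplicative
    drift common to both channels cancels in the ratio, dR/R is
    invariant to common-mode drift.
    """
    sig = np.asarray(signal_trace, dtype=float)
    struct = np.asarray(structural_trace, dtype=float)
    if sig.shape != struct.shape:
        raise ValueError("channel traces must have equal length")
    if np.any(struct <= 0):
        raise ValueError("structural channel must be strictly positive")
    r = sig / struct
    r0 = rolling_lower_quartile_baseline(r, frame_rate_hz, window_s, baseline_fraction)
    if np.any(r0 <= 0):
        raise ValueError("baseline R0 is nonpositive; trace unsuitable for dR/R")
    return (r - r0) / r0
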