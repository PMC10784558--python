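"""Signal conditioning: background subtraction then sliding-average smoothing."""

from __future__ import annotations

import numpy as np

from .signal import DLSignal

__all__ = ["subtract_background", "moving_average"]


def subtract_background(signal: DLSignal, background: float) -> DLSignal:
    """Remove a constant per-bin background level.

    Values may go negative; no clipping is applied.
    """
    if background < 0:
        raise ValueError("background must be non-negative")
    return signal.with_values(signal.values - background, background_subtracted=background)


def moving_average(signal: DLSignal, window: int = 5) -> DLSignal:
    """Centered sliding mean with window truncation at the edges.

    The window must be odd so the mean is centered; near the boundaries it
    shrinks to the samples actually available, so the output has the same
    length as the input.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    n = len(signal)
    if window > n:
        raise ValueError("window exceeds signal length")
    half = window // 2
    # cumulative-sum formulation of the truncated centered mean
    csum = np.concatenate(([0.0], np.cumsum(signal.values)))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    smoothed = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return signal.with_values(smoothed, smoothing_window=window)
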