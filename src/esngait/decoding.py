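"""Convert continuous readout signals into discrete event predictions.

The peak decoder keeps strict local maxima (plateaus resolve to their
leftmost sample), discards candidates below ``min_height``, and enforces a
refractory window of ``floor(peak_factor * tau_s * fs)`` samples by greedy
highest-first selection: any candidate within the window of an already
kept, higher peak is dropped.
"""

from __future__ import annotations

import numpy as np

from esngait.core_io import EventPredictions


def local_maxima(x: np.ndarray) -> np.ndarray:
    """Strict local maxima of a 1-D signal; plateau peaks yield their leftmost sample.

    Endpoints are never peaks.
    """
    x = np.asarray(x, dtype=float)
    peaks = []
    i = 1
    while i < x.size - 1:
        if x[i] > x[i - 1]:
            j = i
            while j + 1 < x.size and x[j + 1] == x[i]:
                j += 1
            if j + 1 < x.size and x[j + 1] < x[i]:
                peaks.append(i)
            i = j + 1
        else:
            i += 1
    return np.array(peaks, dtype=np.int64)


def select_peaks(x: np.ndarray, min_distance: int, min_height: float = 0.0) -> np.ndarray:
    """Refractory peak selection on one channel.

    Candidates are strict local maxima with value >= ``min_height``; peaks
    are kept highest-first and any candidate within ``min_distance`` samples
    of a kept peak is discarded.  Ties in height break to the earlier index.
    Returned indices are sorted ascending.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    cand = local_maxima(x)
    cand = cand[x[cand] >= min_height]
    if cand.size == 0 or min_distance <= 0:
        return cand
    order = cand[np.lexsort((cand, -x[cand]))]  # height desc, index asc
    kept: list[int] = []
    for idx in order:
        if all(abs(idx - k) >= min_distance for k in kept):
            kept.append(int(idx))
    return np.array(sorted(kept), dtype=np.int64)


def detect_events(predictions: np.ndarray, classes: list[str], tau_s: float,
                  fs: float, peak_factor: float = 0.65,
                  min_height: float = 0.0, offset: int = 0) -> EventPredictions:
    """Decode per-class event indices from an ``(Nout, T)`` readout matrix.

    ``offset`` shifts returned indices to absolute sample positions (e.g.
    by the transient cut).  Each class channel is decoded independently.
    """
    predictions = np.atleast_2d(np.asarray(predictions, dtype=float))
    if predictions.shape[0] != len(classes):
        raise ValueError("one readout channel per class required")
    if not tau_s > 0:
        raise ValueError("tau_s must be positive")
    if not 0 < peak_factor < 1:
        raise ValueError("peak_factor must be in (0, 1)")
    distance = int(np.floor(peak_factor * tau_s * fs))
    indices = [select_peaks(row, distance, min_height) + offset
               for row in predictions]
    return EventPredictions(list(classes), indices, fs)


def nrmse(predictions: np.ndarray, targets: np.ndarray,
          channel_sum_inside_root: bool = False) -> float:
    """Normalized RMSE of a multi-channel prediction against its target.

    Default reading: per channel, root of (mean squared error / target
    variance), summed over channels.  With ``channel_sum_inside_root`` the
    channel sum is taken before the square root instead.
    """
    predictions = np.atleast_2d(np.asarray(predictions, dtype=float))
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if predictions.shape != targets.shape:
        raise ValueError(f"shape mismatch: {predictions.shape} vs {targets.shape}")
    var = targets.var(axis=1)
    if np.any(var <= 0):
        bad = int(np.argmax(var <= 0))
        raise ValueError(f"target channel {bad} has zero variance")
    terms = ((predictions - targets) ** 2).mean(axis=1) / var
    if channel_sum_inside_root:
        return float(np.sqrt(terms.sum()))
    return float(np.sqrt(terms).sum())


def nrmse_aggregate(per_series: list[float]) -> float:
    """Mean NRMSE over series."""
    if not per_series:
        raise ValueError("need at least one series")
    return float(np.mean(per_series))
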