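"""Teager-Kaiser energy operator comparator for HS and TO detection.

Pipeline: the core operator ``psi[u](n) = u(n)^2 - u(n-1)*u(n+1)`` is
smoothed (moving average) and half-wave rectified into an energy signal.
HS events are the refractory peaks of that energy, with the minimum
inter-peak distance set to 0.7 of the lag of the energy's first
autocorrelation peak.  TO events are found the same way on a modified
energy in which a window around each detected HS has been zeroed and the
signal re-smoothed.

This detector is untrained: it assumes the heel-strike peak dominates the
toe-off peak, and degrades when that assumption is inverted.
"""

from __future__ import annotations

import warnings

import numpy as np

from esngait.core_io import TimeseriesRecord
from esngait.decoding import select_peaks

#: Fraction of the first autocorrelation lag used as minimum peak distance.
DISTANCE_FACTOR = 0.7

#: Half-width of the HS suppression window as a fraction of the lag.
SUPPRESS_FRACTION = 0.15

#: Smallest lag (seconds) considered when searching autocorrelation peaks.
MIN_LAG_S = 0.25


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    pad = window // 2
    xp = np.pad(x.astype(float), pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(xp, kernel, mode="same")[pad:pad + x.size]


def tk_energy(u: TimeseriesRecord, smooth_window_s: float = 0.05) -> np.ndarray:
    """Smoothed, rectified Teager-Kaiser energy of a single-channel record.

    Interior samples apply the core operator; the boundary samples
    replicate their nearest interior value.  Negative values after
    smoothing are clamped to zero.
    """
    if u.n_channels != 1:
        raise ValueError("tk_energy expects a single-channel record")
    x = u.data[0]
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    core = np.empty_like(x, dtype=float)
    core[1:-1] = x[1:-1] ** 2 - x[:-2] * x[2:]
    core[0] = core[1]
    core[-1] = core[-2]
    window = max(1, int(round(smooth_window_s * u.fs)))
    return np.clip(_moving_average(core, window), 0.0, None)


def first_autocorrelation_peak(phi: np.ndarray, fs: float,
                               min_lag_s: float = MIN_LAG_S,
                               height_fraction: float = 0.5) -> int:
    """Lag (samples) of the first dominant local maximum of the biased
    autocorrelation of the mean-removed signal, at lags >= ``min_lag_s``.

    Minor bumps caused by within-cycle secondary peaks (e.g. the HS-to-TO
    spacing) are skipped: a candidate must reach ``height_fraction`` of the
    tallest local maximum to count as the period peak.
    """
    phi = np.asarray(phi, dtype=float)
    z = phi - phi.mean()
    n = z.size
    # biased autocorrelation via FFT
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(z, nfft)
    r = np.fft.irfft(spec * np.conj(spec), nfft)[:n] / n
    lag0 = max(1, int(round(min_lag_s * fs)))
    maxima = [lag for lag in range(lag0, n - 1)
              if r[lag] > r[lag - 1] and r[lag] >= r[lag + 1]]
    if not maxima:
        raise ValueError("no autocorrelation peak found; the signal may be "
                         "aperiodic or too short")
    floor = height_fraction * max(r[lag] for lag in maxima)
    for lag in maxima:
        if r[lag] >= floor:
            return lag
    raise ValueError("no dominant autocorrelation peak found")


def detect_hs_tkeo(phi: np.ndarray, fs: float) -> np.ndarray:
    """HS indices: refractory peaks of the energy signal."""
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0):
        raise ValueError("energy signal must be non-negative")
    lag = first_autocorrelation_peak(phi, fs)
    distance = int(np.floor(DISTANCE_FACTOR * lag))
    return select_peaks(phi, distance)


def detect_to_tkeo(phi: np.ndarray, hs_indices: np.ndarray, fs: float,
                   suppress_fraction: float = SUPPRESS_FRACTION,
                   smooth_window_s: float = 0.05) -> np.ndarray:
    """TO indices: peaks of the energy after suppressing the HS peaks.

    A window of ``+/- suppress_fraction * lag`` samples around each HS index
    is zeroed, the signal is re-smoothed, and peaks are selected with the
    minimum distance derived from the modified signal's own first
    autocorrelation peak.
    """
    phi = np.asarray(phi, dtype=float)
    hs_indices = np.asarray(hs_indices, dtype=np.int64)
    if hs_indices.size == 0:
        raise ValueError("hs_indices must be non-empty")
    lag = first_autocorrelation_peak(phi, fs)
    half = int(round(suppress_fraction * lag))
    psi = phi.copy()
    for hs in hs_indices:
        psi[max(0, hs - half):min(psi.size, hs + half + 1)] = 0.0
    window = max(1, int(round(smooth_window_s * fs)))
    psi = _moving_average(psi, window)
    if psi.max() < 1e-6 * max(phi.max(), 1e-300):
        warnings.warn("residual energy after HS suppression is negligible; "
                      "no TO events detected", stacklevel=2)
        return np.array([], dtype=np.int64)
    lag2 = first_autocorrelation_peak(psi, fs)
    distance = int(np.floor(DISTANCE_FACTOR * lag2))
    return select_peaks(psi, distance)


def detect_events_tkeo(u: TimeseriesRecord,
                       smooth_window_s: float = 0.05) -> dict[str, np.ndarray]:
    """Full comparator pipeline on a single-channel record -> HS/TO indices."""
    phi = tk_energy(u, smooth_window_s)
    hs = detect_hs_tkeo(phi, u.fs)
    to = detect_to_tkeo(phi, hs, u.fs, smooth_window_s=smooth_window_s)
    return {"HS": hs, "TO": to}
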