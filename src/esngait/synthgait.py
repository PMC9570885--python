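"""Synthetic quasi-periodic gait signals with known ground-truth events.

Generates per cycle: an acceleration trace with a dominant sharp
heel-strike peak, a smaller toe-off peak, a low-amplitude swing
oscillation and near-zero mid-stance; plus heel/toe force channels whose
landmarks encode the six event classes:

* HS — heel force rises through the contact threshold,
* HP — first local maximum of total (heel + toe) force,
* FF — minimum of total force between the two maxima,
* HO — heel force falls through the contact threshold,
* TP — second local maximum of total force,
* TO — toe force falls through the contact threshold.

Waveform shapes are analytic templates tuned so that each landmark falls
exactly at its nominal event phase (contact threshold 5 % of the channel
maximum).  Randomness comes from a seeded ``numpy.random.default_rng``
(PCG64); identical specs produce bitwise-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from esngait.core_io import EVENT_CLASSES, EventTargets, TimeseriesRecord

#: Relative force level at which contact thresholds are placed; waveforms
#: are shaped so threshold crossings occur exactly at the event phases.
CONTACT_LEVEL = 0.05

_DEFAULT_PHASES: dict[str, float] = {
    "HS": 0.00, "HP": 0.08, "FF": 0.25, "HO": 0.40, "TP": 0.50, "TO": 0.62,
}

_AXIS_NAMES = ("AP", "V", "ML")


@dataclass
class GaitSimSpec:
    """Parameters of one synthetic recording."""

    fs: float = 200.0
    duration_s: float = 60.0
    cadence_hz: float = 1.0
    cycle_jitter: float = 0.0   # CoV of cycle length
    amp_jitter: float = 0.0     # CoV of per-cycle peak amplitudes
    noise_sd: float = 0.0       # additive white Gaussian noise SD
    event_phases: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PHASES))
    hs_peak_gain: float = 2.0
    to_peak_gain: float = 1.0
    n_channels: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0 or self.cadence_hz <= 0:
            raise ValueError("fs, duration_s and cadence_hz must be positive")
        if self.cycle_jitter < 0 or self.amp_jitter < 0 or self.noise_sd < 0:
            raise ValueError("jitter and noise parameters must be >= 0")
        if not 1 <= self.n_channels <= 3:
            raise ValueError("n_channels must be 1, 2 or 3")
        missing = set(EVENT_CLASSES) - set(self.event_phases)
        if missing:
            raise ValueError(f"event_phases missing classes: {sorted(missing)}")
        phases = [self.event_phases[c] for c in EVENT_CLASSES]
        if any(not 0 <= p < 1 for p in phases):
            raise ValueError("event phases must lie in [0, 1)")
        if any(b <= a for a, b in zip(phases, phases[1:])):
            raise ValueError(
                "event phases must be strictly increasing in HS<HP<FF<HO<TP<TO order")
        if self.event_phases["HS"] != 0.0:
            raise ValueError("HS phase must be 0 by convention")
        if self.duration_s * self.cadence_hz < 3:
            raise ValueError("spec must cover at least 3 gait cycles")


def _gaussian_bump(n: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((n - center) / sigma) ** 2)


def _heel_profile(u: np.ndarray, ph: dict[str, float]) -> np.ndarray:
    """Heel force over one cycle as a function of cycle phase ``u``.

    Linear rise through CONTACT_LEVEL at HS up to 1 at HP, partial cosine
    fall to a plateau ``c`` at FF, plateau, then cosine release shaped so the
    downward CONTACT_LEVEL crossing lands exactly at HO.
    """
    c = 2 * CONTACT_LEVEL  # plateau level; release crossing sits at its midpoint
    hp, ff, ho = ph["HP"], ph["FF"], ph["HO"]
    a = CONTACT_LEVEL * hp / (1 - CONTACT_LEVEL)  # pre-rise so value at HS == level
    mid = 0.5 * (ff + ho)
    end = 2 * ho - mid  # cosine midpoint (= c/2 = CONTACT_LEVEL) falls at HO
    out = np.zeros_like(u)

    m = (u >= -a) & (u < hp)
    out[m] = (u[m] + a) / (hp + a)
    m = (u >= hp) & (u < ff)
    out[m] = c + (1 - c) * np.cos(0.5 * np.pi * (u[m] - hp) / (ff - hp))
    m = (u >= ff) & (u < mid)
    out[m] = c
    m = (u >= mid) & (u < end)
    out[m] = c * 0.5 * (1 + np.cos(np.pi * (u[m] - mid) / (end - mid)))
    return out


def _toe_profile(u: np.ndarray, ph: dict[str, float]) -> np.ndarray:
    """Toe force: quarter-sine rise FF -> TP, cosine release crossing at TO."""
    ff, tp, to = ph["FF"], ph["TP"], ph["TO"]
    # choose release span so the CONTACT_LEVEL crossing lands exactly at TO
    w_to = math.acos(2 * CONTACT_LEVEL - 1) / math.pi
    end = tp + (to - tp) / w_to
    out = np.zeros_like(u)

    m = (u >= ff) & (u < tp)
    out[m] = np.sin(0.5 * np.pi * (u[m] - ff) / (tp - ff))
    m = (u >= tp) & (u < end)
    out[m] = 0.5 * (1 + np.cos(np.pi * (u[m] - tp) / (end - tp)))
    return out


def generate_gait(spec: GaitSimSpec) -> tuple[TimeseriesRecord, TimeseriesRecord, EventTargets]:
    """Generate one synthetic recording.

    Returns
    -------
    acceleration : TimeseriesRecord
        ``n_channels x T`` matrix; first channel is the primary (AP) axis.
    forces : TimeseriesRecord
        Two channels labelled ``heel`` and ``toe``.
    truth : EventTargets
        Exactly one index per class per complete cycle.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.fs
    T = int(round(spec.duration_s * fs))
    period = fs / spec.cadence_hz

    # integer cycle lengths; quantization makes the jitter-free case exactly periodic
    start0 = int(round(0.05 * period))
    starts: list[int] = []
    lengths: list[int] = []
    pos = start0
    while True:
        L = int(round(period * max(0.5, 1.0 + spec.cycle_jitter * rng.standard_normal())))
        if pos + L > T:
            break
        starts.append(pos)
        lengths.append(L)
        pos += L
    if len(starts) < 3:
        raise ValueError(f"spec yields only {len(starts)} complete cycles; need >= 3")

    ph = spec.event_phases
    n = np.arange(T, dtype=float)
    accel = np.zeros((spec.n_channels, T))
    heel = np.zeros(T)
    toe = np.zeros(T)
    truth_idx: dict[str, list[int]] = {c: [] for c in EVENT_CLASSES}

    # per-channel tweaks for secondary axes (scaled variants of the primary)
    hs_gain_ch = (1.0, 0.7, 0.45)[: spec.n_channels]
    to_gain_ch = (1.0, 1.2, 0.6)[: spec.n_channels]

    for s, L in zip(starts, lengths):
        amp = max(0.1, 1.0 + spec.amp_jitter * rng.standard_normal())
        amp_f = max(0.1, 1.0 + spec.amp_jitter * rng.standard_normal())

        for c in EVENT_CLASSES:
            truth_idx[c].append(s + int(round(ph[c] * L)))

        lo = max(0, s - int(math.ceil(0.1 * L)))
        hi = min(T, s + L)
        u = (n[lo:hi] - s) / L

        heel[lo:hi] += amp_f * _heel_profile(u, ph)
        toe[lo:hi] += 0.9 * amp_f * _toe_profile(u, ph)

        hs_center = float(s)
        to_center = s + ph["TO"] * L
        swing = np.zeros_like(u)
        m = u >= ph["TO"]
        v = (u[m] - ph["TO"]) / (1.0 - ph["TO"])
        swing[m] = 0.15 * np.sin(2 * np.pi * 2 * v) * np.sin(np.pi * v)
        for ci in range(spec.n_channels):
            accel[ci, lo:hi] += (
                amp * spec.hs_peak_gain * hs_gain_ch[ci]
                * _gaussian_bump(n[lo:hi], hs_center, 0.012 * L)
                + amp * spec.to_peak_gain * to_gain_ch[ci]
                * _gaussian_bump(n[lo:hi], to_center, 0.035 * L)
                + amp * spec.hs_peak_gain * swing
            )

    if spec.noise_sd > 0:
        accel += spec.noise_sd * rng.standard_normal(accel.shape)
        heel += spec.noise_sd * rng.standard_normal(T)
        toe += spec.noise_sd * rng.standard_normal(T)

    meta = {"generator": "esngait.synthgait/v1", "seed": spec.seed,
            "cadence_hz": spec.cadence_hz}
    acceleration = TimeseriesRecord(
        accel, fs, list(_AXIS_NAMES[: spec.n_channels]), dict(meta))
    forces = TimeseriesRecord(np.vstack([heel, toe]), fs, ["heel", "toe"], dict(meta))
    truth = EventTargets(
        list(EVENT_CLASSES),
        [np.array(truth_idx[c], dtype=np.int64) for c in EVENT_CLASSES],
        T,
    )
    return acceleration, forces, truth


def make_dataset(specs: list[GaitSimSpec]) -> list[tuple[TimeseriesRecord, TimeseriesRecord, EventTargets]]:
    """Generate one (acceleration, forces, truth) triple per spec."""
    if not specs:
        raise ValueError("specs must be a non-empty list")
    return [generate_gait(s) for s in specs]
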