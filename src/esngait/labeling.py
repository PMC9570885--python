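"""Derive target gait events from force signals and split train/test sets.

Event semantics (per cycle, one index per class per complete stance):

* HS — heel force first rises through the contact threshold,
* HP — first local maximum of total (heel + toe) force after HS,
* FF — minimum of total force between the two maxima,
* HO — heel force falls back through the contact threshold,
* TP — second (last) local maximum of total force,
* TO — toe force falls through the contact threshold.

Contact thresholds are a configurable fraction of the per-record channel
maximum, with hysteresis (rearm only after the force falls below half the
threshold) to suppress chatter.  Local extrema are located on the smoothed
total force; ties break to the earliest index.  Cycles with incomplete
stance at the record edges are discarded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from esngait.core_io import EVENT_CLASSES, EventTargets, TimeseriesRecord

logger = logging.getLogger(__name__)


@dataclass
class LabelingConfig:
    contact_threshold_frac: float = 0.05
    smooth_window_s: float = 0.05
    classes: list[str] = field(default_factory=lambda: list(EVENT_CLASSES))

    def __post_init__(self) -> None:
        if not 0 < self.contact_threshold_frac < 0.5:
            raise ValueError("contact_threshold_frac must be in (0, 0.5)")
        if self.smooth_window_s < 0:
            raise ValueError("smooth_window_s must be >= 0")
        unknown = set(self.classes) - set(EVENT_CLASSES)
        if unknown:
            raise ValueError(f"unknown classes: {sorted(unknown)}")
        self.classes = [c for c in EVENT_CLASSES if c in self.classes]


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x.astype(float), pad, mode="edge")
    return np.convolve(xp, kernel, mode="same")[pad:pad + x.size]


def _threshold_crossings(x: np.ndarray, threshold: float) -> tuple[np.ndarray, np.ndarray]:
    """Rising/falling crossings of ``threshold`` with half-threshold hysteresis.

    Returns (rising, falling) sample indices: the first sample at/above the
    threshold and the first sample below it, respectively.
    """
    rising, falling = [], []
    state = x[0] >= threshold
    armed = x[0] < 0.5 * threshold
    for i in range(1, x.size):
        if not state:
            if x[i] < 0.5 * threshold:
                armed = True
            if armed and x[i] >= threshold:
                rising.append(i)
                state = True
                armed = False
        elif x[i] < threshold:
            falling.append(i)
            state = False
    return np.array(rising, dtype=np.int64), np.array(falling, dtype=np.int64)


def label_events_from_force(heel: TimeseriesRecord, toe: TimeseriesRecord,
                            cfg: LabelingConfig | None = None) -> EventTargets:
    """Extract gait event targets from heel/toe force channels.

    ``heel`` and ``toe`` must be single-channel records of equal length and
    sampling rate.  Cycles in which a requested landmark cannot be located
    are skipped (and logged).  All-zero forces yield empty targets.
    """
    cfg = cfg or LabelingConfig()
    if heel.n_channels != 1 or toe.n_channels != 1:
        raise ValueError("heel and toe must be single-channel records")
    if heel.n_samples != toe.n_samples or heel.fs != toe.fs:
        raise ValueError("heel and toe must share length and sampling rate")
    fs = heel.fs
    T = heel.n_samples
    window = max(1, int(round(cfg.smooth_window_s * fs)))
    h = _smooth(heel.data[0], window)
    t = _smooth(toe.data[0], window)
    total = h + t

    if h.max() <= 0 and t.max() <= 0:
        warnings.warn("all-zero force signals: no events extracted", stacklevel=2)
        return EventTargets(list(cfg.classes), [np.array([], dtype=np.int64)
                                                for _ in cfg.classes], T)

    th_heel = cfg.contact_threshold_frac * h.max()
    th_toe = cfg.contact_threshold_frac * t.max()
    heel_rise, heel_fall = _threshold_crossings(h, th_heel)
    _, toe_fall = _threshold_crossings(t, th_toe)

    found: dict[str, list[int]] = {c: [] for c in cfg.classes}
    n_skipped = 0
    for j, hs in enumerate(heel_rise):
        cycle_end = heel_rise[j + 1] if j + 1 < heel_rise.size else T
        ev: dict[str, int] = {"HS": int(hs)}

        ho_c = heel_fall[(heel_fall > hs) & (heel_fall < cycle_end)]
        to_c = toe_fall[(toe_fall > hs) & (toe_fall < cycle_end)]
        if ho_c.size:
            ev["HO"] = int(ho_c[0])
        if to_c.size:
            ev["TO"] = int(to_c[0])

        stance_end = ev.get("TO", cycle_end)
        seg = total[hs:stance_end]
        if seg.size >= 3:
            prominence = 0.05 * (seg.max() - seg.min()) if seg.max() > seg.min() else None
            peaks, _ = find_peaks(seg, prominence=prominence)
            if peaks.size >= 2:
                ev["HP"] = int(hs + peaks[0])
                ev["TP"] = int(hs + peaks[-1])
                valley = seg[peaks[0]:peaks[-1] + 1]
                ev["FF"] = int(hs + peaks[0] + np.argmin(valley))

        missing = [c for c in cfg.classes if c not in ev]
        ordered = [ev[c] for c in EVENT_CLASSES if c in ev and c in cfg.classes]
        if missing or any(b <= a for a, b in zip(ordered, ordered[1:])):
            n_skipped += 1
            logger.debug("cycle at sample %d skipped (missing %s)", hs, missing)
            continue
        for c in cfg.classes:
            found[c].append(ev[c])

    if n_skipped:
        logger.info("skipped %d incomplete cycles while labeling", n_skipped)
    return EventTargets(list(cfg.classes),
                        [np.array(found[c], dtype=np.int64) for c in cfg.classes], T)


def make_indicator(indices: dict[str, np.ndarray] | list[np.ndarray], T: int,
                   classes: list[str]) -> EventTargets:
    """Build a binary indicator target from per-class event index lists.

    Row ``i`` of the indicator has a 1 exactly at each index of class
    ``classes[i]`` and 0 elsewhere.  Raises on out-of-range or duplicate
    indices.
    """
    if isinstance(indices, dict):
        per_class = [np.asarray(indices.get(c, []), dtype=np.int64) for c in classes]
    else:
        per_class = [np.asarray(i, dtype=np.int64) for i in indices]
    for c, idx in zip(classes, per_class):
        if np.unique(idx).size != idx.size:
            raise ValueError(f"{c}: duplicate event index")
    return EventTargets(list(classes), [np.sort(i) for i in per_class], T)


def middle_stance_indices(targets: EventTargets, database_style: str = "HS_TO_mean") -> np.ndarray:
    """Mid-stance-phase (MSP) indices used to cut train/test segments.

    ``HS_TO_mean`` pairs each HS with the next TO before the following HS
    and returns the rounded mean index; unpaired trailing HS cycles are
    excluded.  ``HO`` and ``FF`` return those event indices directly.
    """
    if database_style in ("HO", "FF"):
        try:
            return targets.indices_for(database_style).copy()
        except KeyError:
            raise ValueError(f"style {database_style!r} requires class "
                             f"{database_style} in targets") from None
    if database_style != "HS_TO_mean":
        raise ValueError("database_style must be HS_TO_mean, HO or FF")
    try:
        hs = targets.indices_for("HS")
        to = targets.indices_for("TO")
    except KeyError as exc:
        raise ValueError("style HS_TO_mean requires HS and TO classes") from exc
    msp = []
    for j, h in enumerate(hs):
        bound = hs[j + 1] if j + 1 < hs.size else np.iinfo(np.int64).max
        cand = to[(to > h) & (to < bound)]
        if cand.size:
            msp.append(int(round(0.5 * (h + cand[0]))))
    return np.array(msp, dtype=np.int64)


def _slice_targets(targets: EventTargets, start: int, stop: int) -> EventTargets:
    idx = [i[(i >= start) & (i < stop)] - start for i in targets.indices]
    return EventTargets(list(targets.classes), idx, stop - start)


def split_train_test(rec: TimeseriesRecord, targets: EventTargets,
                     msp: np.ndarray, frac: float = 0.7,
                     ) -> tuple[tuple[TimeseriesRecord, EventTargets],
                                tuple[TimeseriesRecord, EventTargets]]:
    """Cut a record at the MSP closest to ``frac`` of its length.

    The training part starts at the first MSP (data before it is dropped so
    both segments begin at the same point of the gait cycle); the test part
    is the remainder.  Target indices are re-expressed relative to each
    segment's start.
    """
    msp = np.asarray(msp, dtype=np.int64)
    if msp.size < 2:
        raise ValueError("need at least 2 MSP indices to split")
    if rec.n_samples != targets.n_samples:
        raise ValueError("record and targets must share length")
    T = rec.n_samples
    split = int(msp[np.argmin(np.abs(msp - frac * T))])
    first = int(msp[0])
    if not first < split:
        raise ValueError("split MSP must lie after the first MSP")
    train = (rec.slice(first, split), _slice_targets(targets, first, split))
    test = (rec.slice(split, T), _slice_targets(targets, split, T))
    return train, test
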