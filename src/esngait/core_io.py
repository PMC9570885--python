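"""Domain types and plain-text readers/writers shared by all modules.

Conventions
-----------
* Time indexing is 0-based sample index; seconds are ``index / fs``.
* Timeseries files are delimited text (comma/tab/whitespace sniffed), one
  row per sample, one column per channel, optional header row of labels.
* Event files are delimited text with columns ``class,sample_index,time_s``
  and a ``# fs=<Hz>`` comment header.
* Model archives are JSON; float64 values survive the round trip exactly.
"""

from __future__ import annotations

import csv
import json
import math
import os
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import resample_poly

#: Canonical ordering of the six gait event classes within a cycle.
EVENT_CLASSES: tuple[str, ...] = ("HS", "HP", "FF", "HO", "TP", "TO")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class TimeseriesRecord:
    """One multi-channel recording at a fixed sampling rate.

    Parameters
    ----------
    data
        Real matrix of shape ``(n_channels, T)``.
    fs
        Sampling rate in Hz, strictly positive.
    channel_labels
        Unique axis names, one per channel (e.g. ``["AP", "ML", "V"]``).
    meta
        Free-form metadata (subject id, condition tag, record index ...).
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (n_channels x T) matrix")
        if self.data.shape[1] < 1 or self.data.shape[0] < 1:
            raise ValueError("need n_channels >= 1 and T >= 1")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return one channel as a 1-D view, selected by label."""
        try:
            i = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"no channel {label!r} in {self.channel_labels}") from None
        return self.data[i]

    def slice(self, start: int, stop: int) -> "TimeseriesRecord":
        """Contiguous sub-record ``[start, stop)``; meta records the offset."""
        if not 0 <= start < stop <= self.n_samples:
            raise ValueError(f"bad slice [{start}, {stop}) for T={self.n_samples}")
        meta = dict(self.meta)
        meta["start_index"] = meta.get("start_index", 0) + start
        return TimeseriesRecord(self.data[:, start:stop].copy(), self.fs,
                                list(self.channel_labels), meta)


@dataclass
class EventTargets:
    """Per-class event sample indices plus the equivalent binary indicator.

    ``indicator`` is an ``(n_classes, T)`` 0/1 matrix with row ``i`` holding
    a 1 exactly at each index in ``indices[i]``.
    """

    classes: list[str]
    indices: list[np.ndarray]
    n_samples: int

    def __post_init__(self) -> None:
        if len(self.classes) != len(self.indices):
            raise ValueError("one index list per class required")
        unknown = set(self.classes) - set(EVENT_CLASSES)
        if unknown:
            raise ValueError(f"unknown event classes: {sorted(unknown)}")
        clean = []
        for cls, idx in zip(self.classes, self.indices):
            idx = np.asarray(idx, dtype=np.int64).ravel()
            if idx.size and (idx.min() < 0 or idx.max() >= self.n_samples):
                raise ValueError(f"{cls}: index out of range [0, {self.n_samples})")
            if idx.size > 1 and np.any(np.diff(idx) <= 0):
                raise ValueError(f"{cls}: indices must be strictly increasing")
            clean.append(idx)
        self.indices = clean

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def indicator(self) -> np.ndarray:
        out = np.zeros((self.n_classes, self.n_samples))
        for row, idx in zip(out, self.indices):
            row[idx] = 1.0
        return out

    def indices_for(self, cls: str) -> np.ndarray:
        try:
            return self.indices[self.classes.index(cls)]
        except ValueError:
            raise KeyError(f"no class {cls!r} in {self.classes}") from None

    def counts(self) -> dict[str, int]:
        return {c: int(i.size) for c, i in zip(self.classes, self.indices)}


@dataclass
class ESNConfig:
    """Echo state network hyperparameters (defaults are the reference set)."""

    N: int = 100
    alpha: float = 0.1053
    rho: float = 0.7471
    P: float = 0.21
    Si: float = 2.300
    Pi: float = 0.41
    Sb: float = 2.911
    gamma: float = 1e-6
    transient_s: float = 1.25
    peak_factor: float = 0.65
    seed: int = 0
    leak_variant: str = "standard"  # "standard": (1-a) retention; "printed": (a-1)

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if not self.rho > 0:
            raise ValueError("rho must be > 0")
        for name in ("P", "Pi"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not 0 < self.peak_factor < 1:
            raise ValueError("peak_factor must be in (0, 1)")
        if self.leak_variant not in ("standard", "printed"):
            raise ValueError("leak_variant must be 'standard' or 'printed'")


@dataclass
class ESNModel:
    """Fixed reservoir matrices plus the trained readout and cycle duration.

    ``Win`` has shape ``(N, n_input_channels + 1)`` — the extra first column
    is the bias path. ``Wout`` and ``tau_s`` are ``None`` before training.
    """

    config: ESNConfig
    Win: np.ndarray
    W: np.ndarray
    Wout: np.ndarray | None = None
    tau_s: float | None = None
    classes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.Win = np.asarray(self.Win, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        N = self.config.N
        if self.W.shape != (N, N):
            raise ValueError(f"W must be {N}x{N}")
        if self.Win.ndim != 2 or self.Win.shape[0] != N or self.Win.shape[1] < 2:
            raise ValueError("Win must be N x (n_input_channels + 1)")
        if self.Wout is not None:
            self.Wout = np.asarray(self.Wout, dtype=float)
            if self.Wout.shape[1] != N:
                raise ValueError("Wout column count must equal N")

    @property
    def n_input_channels(self) -> int:
        return self.Win.shape[1] - 1

    @property
    def is_trained(self) -> bool:
        return self.Wout is not None and self.tau_s is not None


@dataclass
class EventPredictions:
    """Decoded event indices per class, at sampling rate ``fs``."""

    classes: list[str]
    indices: list[np.ndarray]
    fs: float

    def __post_init__(self) -> None:
        if len(self.classes) != len(self.indices):
            raise ValueError("one index list per class required")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        clean = []
        for cls, idx in zip(self.classes, self.indices):
            idx = np.asarray(idx, dtype=np.int64).ravel()
            if idx.size > 1 and np.any(np.diff(idx) <= 0):
                raise ValueError(f"{cls}: indices must be strictly increasing")
            clean.append(idx)
        self.indices = clean

    def indices_for(self, cls: str) -> np.ndarray:
        try:
            return self.indices[self.classes.index(cls)]
        except ValueError:
            raise KeyError(f"no class {cls!r} in {self.classes}") from None

    def counts(self) -> dict[str, int]:
        return {c: int(i.size) for c, i in zip(self.classes, self.indices)}


# ---------------------------------------------------------------------------
# timeseries io
# ---------------------------------------------------------------------------


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",;\t ").delimiter
    except csv.Error:
        return ","


def _is_number(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True


def read_timeseries(path: str | os.PathLike, fs: float | None = None,
                    channel_labels: Sequence[str] | None = None) -> TimeseriesRecord:
    """Read a delimited-text timeseries: one row per sample, one column per channel.

    A non-numeric first row is treated as a header of channel labels;
    explicit ``channel_labels`` override it.  ``fs`` may be omitted when the
    file carries a ``# fs=<Hz>`` comment header.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path, newline="") as fh:
        text = fh.read()
    for ln in text.splitlines():
        stripped = ln.lstrip()
        if stripped.startswith("#") and stripped[1:].strip().startswith("fs="):
            header_fs = float(stripped[1:].strip()[3:])
            if fs is None:
                fs = header_fs
    if fs is None:
        raise ValueError(f"{path}: no fs given and no '# fs=' header present")
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty file")
    delim = _sniff_delimiter(lines[0])
    rows = [[tok for tok in ln.split(delim) if tok.strip() != ""] for ln in lines]

    header: list[str] | None = None
    if any(not _is_number(tok) for tok in rows[0]):
        header = [tok.strip() for tok in rows[0]]
        rows = rows[1:]
        if not rows:
            raise ValueError(f"{path}: header but no data rows")

    ncol = len(rows[0])
    data = np.empty((len(rows), ncol))
    for r, row in enumerate(rows):
        if len(row) != ncol:
            raise ValueError(f"{path}: ragged row {r} ({len(row)} columns, expected {ncol})")
        for c, tok in enumerate(row):
            try:
                data[r, c] = float(tok)
            except ValueError:
                raise ValueError(f"{path}: non-numeric cell at row {r}, column {c}: {tok!r}") from None

    labels = list(channel_labels) if channel_labels is not None else header
    return TimeseriesRecord(data.T, fs=fs, channel_labels=labels or [],
                            meta={"source": path})


def write_timeseries(path: str | os.PathLike, rec: TimeseriesRecord,
                     delimiter: str = ",") -> None:
    """Write a record as delimited text with a header row of channel labels."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# fs={rec.fs!r}\n")
        fh.write(delimiter.join(rec.channel_labels) + "\n")
        for row in rec.data.T:
            fh.write(delimiter.join(repr(float(v)) for v in row) + "\n")


def resample_record(rec: TimeseriesRecord, target_fs: float) -> TimeseriesRecord:
    """Polyphase (rational-ratio, anti-aliased) resampling to ``target_fs``.

    Output length is ``round(T * target_fs / fs)``.
    """
    if not target_fs > 0:
        raise ValueError("target_fs must be positive")
    if math.isclose(target_fs, rec.fs):
        return TimeseriesRecord(rec.data.copy(), target_fs,
                                list(rec.channel_labels), dict(rec.meta))
    ratio = Fraction(target_fs / rec.fs).limit_denominator(10_000)
    if ratio <= 0:
        raise ValueError("resampling ratio must be positive and rational")
    # kaiser beta 10 keeps passband ripple low enough for ~1e-5 round trips
    out = resample_poly(rec.data, ratio.numerator, ratio.denominator, axis=1,
                        padtype="line", window=("kaiser", 10.0))
    n_out = int(round(rec.n_samples * target_fs / rec.fs))
    if out.shape[1] < n_out:  # pad with edge value on rare length mismatch
        out = np.pad(out, ((0, 0), (0, n_out - out.shape[1])), mode="edge")
    out = out[:, :n_out]
    return TimeseriesRecord(out, target_fs, list(rec.channel_labels), dict(rec.meta))


# ---------------------------------------------------------------------------
# event io
# ---------------------------------------------------------------------------


def write_events(path: str | os.PathLike,
                 events: EventTargets | EventPredictions,
                 fs: float | None = None) -> None:
    """Write events as ``class,sample_index,time_s`` rows with a ``# fs=`` header."""
    if fs is None:
        fs = getattr(events, "fs", None)
    if fs is None:
        raise ValueError("fs required to write EventTargets")
    with open(path, "w", newline="") as fh:
        fh.write(f"# fs={fs!r}\n")
        if isinstance(events, EventTargets):
            fh.write(f"# n_samples={events.n_samples}\n")
        fh.write("class,sample_index,time_s\n")
        for cls, idx in zip(events.classes, events.indices):
            for i in idx:
                fh.write(f"{cls},{int(i)},{i / fs!r}\n")


def read_events(path: str | os.PathLike,
                kind: str = "predictions") -> EventTargets | EventPredictions:
    """Read an event file written by :func:`write_events`.

    ``kind`` selects the returned type: ``"predictions"`` or ``"targets"``
    (targets require the ``# n_samples=`` header).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fs: float | None = None
    n_samples: int | None = None
    by_class: dict[str, list[int]] = {}
    with open(path, newline="") as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("fs="):
                    fs = float(body[3:])
                elif body.startswith("n_samples="):
                    n_samples = int(body[10:])
                continue
            parts = [p.strip() for p in line.split(",")]
            if parts[0] == "class":
                continue
            cls = parts[0]
            if cls not in EVENT_CLASSES:
                raise ValueError(f"{path}: unknown class label {cls!r}")
            by_class.setdefault(cls, []).append(int(parts[1]))
    if fs is None:
        raise ValueError(f"{path}: missing '# fs=' header")
    classes = [c for c in EVENT_CLASSES if c in by_class]
    indices = [np.array(sorted(by_class[c]), dtype=np.int64) for c in classes]
    for c, idx in zip(classes, indices):
        if idx.size > 1 and np.any(np.diff(idx) <= 0):
            raise ValueError(f"{path}: duplicate index in class {c}")
    if kind == "predictions":
        return EventPredictions(classes, indices, fs)
    if kind == "targets":
        if n_samples is None:
            n_samples = int(max((i[-1] for i in indices if i.size), default=0)) + 1
        return EventTargets(classes, indices, n_samples)
    raise ValueError("kind must be 'predictions' or 'targets'")


# ---------------------------------------------------------------------------
# model io
# ---------------------------------------------------------------------------


def write_model(path: str | os.PathLike, model: ESNModel) -> None:
    """Serialize a model to JSON (exact float64 round trip)."""
    cfg = model.config
    payload = {
        "format": "esngait-model-v1",
        "config": {k: getattr(cfg, k) for k in (
            "N", "alpha", "rho", "P", "Si", "Pi", "Sb", "gamma",
            "transient_s", "peak_factor", "seed", "leak_variant")},
        "Win": model.Win.tolist(),
        "W": model.W.tolist(),
        "Wout": None if model.Wout is None else model.Wout.tolist(),
        "tau_s": model.tau_s,
        "classes": list(model.classes),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_model(path: str | os.PathLike) -> ESNModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "esngait-model-v1":
        raise ValueError(f"{path}: not a model archive")
    cfg = ESNConfig(**payload["config"])
    wout = payload["Wout"]
    return ESNModel(
        config=cfg,
        Win=np.array(payload["Win"], dtype=float),
        W=np.array(payload["W"], dtype=float),
        Wout=None if wout is None else np.array(wout, dtype=float),
        tau_s=payload["tau_s"],
        classes=list(payload["classes"]),
    )
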