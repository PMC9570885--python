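"""Event-level detection scoring.

Workflow per event class:

1. :func:`match_errors` — one signed error per target event
   (target time minus nearest prediction time).
2. :func:`remove_median_bias` — subtract, per class, the median error
   pooled over all timeseries.
3. :func:`classify_outcomes` — split events into TP / FN by a tolerance
   (default 65 ms); FP is the residual count of predictions over TPs and
   TN the remaining time points.
4. :func:`rates` — TPR, PPV, their harmonic mean T1, and SPF.

Timing precision is summarized by :func:`mae_per_series` (per-series mean
absolute centered error) or, for literature-style comparison,
:func:`mae_tp_only` (mean/sd over errors within a 40 ms window).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from esngait.core_io import EventPredictions, EventTargets

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD_S = 0.065
TP_ONLY_THRESHOLD_S = 0.040


@dataclass
class OutcomeCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0
    TN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError(f"negative outcome count: {self}")


@dataclass
class DetectionReport:
    """Per-class scoring results for one evaluated dataset."""

    classes: list[str]
    errors: dict[str, list[np.ndarray]]          # centered errors per series (s)
    counts: dict[str, OutcomeCounts]
    rates: dict[str, dict[str, float]]           # TPR/PPV/T1/SPF per class
    mae: dict[str, dict[int, float]]             # class -> series -> MAE (s)
    mae_summary: dict[str, dict[str, float]]
    fs: float
    total_samples: int
    threshold_s: float = DEFAULT_THRESHOLD_S
    median_bias_s: dict[str, float] = field(default_factory=dict)


def match_errors(targets: EventTargets, preds: EventPredictions,
                 fs: float) -> dict[str, np.ndarray]:
    """Signed timing error for each target event, in seconds.

    Error = target time minus time of the closest prediction of the same
    class.  Classes with zero predictions produce ``+inf`` sentinels (all
    counted FN downstream).  Classes present only in the predictions are
    returned with an empty error vector (their predictions become FPs).
    """
    out: dict[str, np.ndarray] = {}
    for cls in set(targets.classes) | set(preds.classes):
        tgt = targets.indices_for(cls) if cls in targets.classes else np.array([], dtype=np.int64)
        prd = preds.indices_for(cls) if cls in preds.classes else np.array([], dtype=np.int64)
        if tgt.size == 0:
            out[cls] = np.array([])
        elif prd.size == 0:
            out[cls] = np.full(tgt.size, np.inf)
        else:
            diff = tgt[:, None] - prd[None, :]
            nearest = np.argmin(np.abs(diff), axis=1)
            out[cls] = diff[np.arange(tgt.size), nearest] / fs
    return out


def remove_median_bias(errors_per_series: list[dict[str, np.ndarray]],
                       ) -> tuple[list[dict[str, np.ndarray]], dict[str, float]]:
    """Subtract the per-class median error pooled over all timeseries.

    Infinite sentinels are left untouched.  Returns the centered error
    structure and the per-class bias that was removed.
    """
    classes = sorted({c for e in errors_per_series for c in e})
    bias: dict[str, float] = {}
    for cls in classes:
        pooled = np.concatenate([e.get(cls, np.array([])) for e in errors_per_series])
        finite = pooled[np.isfinite(pooled)]
        bias[cls] = float(np.median(finite)) if finite.size else 0.0
    centered = []
    for e in errors_per_series:
        ce = {}
        for cls, vec in e.items():
            vec = vec.copy()
            mask = np.isfinite(vec)
            vec[mask] -= bias[cls]
            ce[cls] = vec
        centered.append(ce)
    return centered, bias


def classify_outcomes(centered_errors: list[np.ndarray],
                      n_predictions: int, total_samples: int,
                      threshold_s: float = DEFAULT_THRESHOLD_S) -> OutcomeCounts:
    """Outcome counts for one class, cumulated over timeseries.

    TP: target events with |error| <= threshold; FN: the rest (including
    unmatched ``inf`` sentinels); FP: total predictions minus TP;
    TN: remaining time points.
    """
    if not threshold_s > 0:
        raise ValueError("threshold_s must be positive")
    pooled = np.concatenate(centered_errors) if centered_errors else np.array([])
    tp = int(np.sum(np.abs(pooled) <= threshold_s))
    fn = int(pooled.size - tp)
    fp = n_predictions - tp
    if fp < 0:
        raise RuntimeError("more TPs than predictions — internal error")
    tn = total_samples - (tp + fp + fn)
    return OutcomeCounts(TP=tp, FP=fp, FN=fn, TN=max(tn, 0))


def rates(counts: OutcomeCounts, printed_variant: bool = False) -> dict[str, float]:
    """TPR, PPV, T1 (harmonic mean) and SPF with 0/0 -> 0 conventions.

    ``printed_variant`` swaps the TPR/PPV denominators (FP <-> FN), an
    alternative form seen in some write-ups; the default is the standard
    name-consistent definition.
    """
    tp, fp, fn, tn = counts.TP, counts.FP, counts.FN, counts.TN
    if printed_variant:
        fp, fn = fn, fp
    tpr = tp / (tp + fn) if tp + fn else 0.0
    ppv = tp / (tp + fp) if tp + fp else 0.0
    t1 = 2 * tpr * ppv / (tpr + ppv) if tpr + ppv else 0.0
    spf = tn / (tn + fp) if tn + fp else 0.0
    return {"TPR": tpr, "PPV": ppv, "T1": t1, "SPF": spf}


def mae_per_series(centered_errors: list[np.ndarray],
                   ) -> tuple[dict[int, float], dict[str, float]]:
    """Per-series mean absolute centered error plus a distribution summary.

    Series without finite errors are skipped (logged).  Whisker bounds
    follow the 1.5 * IQR convention.
    """
    mae: dict[int, float] = {}
    for k, vec in enumerate(centered_errors):
        finite = vec[np.isfinite(vec)]
        if finite.size == 0:
            logger.info("series %d has no finite errors; skipped in MAE", k)
            continue
        mae[k] = float(np.mean(np.abs(finite)))
    if not mae:
        return mae, {}
    vals = np.array(list(mae.values()))
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    iqr = q3 - q1
    summary = {
        "median": float(med), "q1": float(q1), "q3": float(q3),
        "mean": float(vals.mean()),
        "whisker_low": float(vals[vals >= q1 - 1.5 * iqr].min()),
        "whisker_high": float(vals[vals <= q3 + 1.5 * iqr].max()),
    }
    return mae, summary


def mae_tp_only(errors: np.ndarray,
                threshold_s: float = TP_ONLY_THRESHOLD_S) -> tuple[float, float]:
    """Mean and SD of |error| restricted to events within ``threshold_s``."""
    if not threshold_s > 0:
        raise ValueError("threshold_s must be positive")
    errors = np.asarray(errors, dtype=float)
    kept = errors[np.isfinite(errors) & (np.abs(errors) <= threshold_s)]
    if kept.size == 0:
        raise ValueError(f"no errors within {threshold_s} s")
    return float(np.mean(np.abs(kept))), float(np.std(np.abs(kept)))


def evaluate_detection(targets_per_series: list[EventTargets],
                       preds_per_series: list[EventPredictions],
                       fs: float,
                       threshold_s: float = DEFAULT_THRESHOLD_S,
                       remove_bias: bool = True) -> DetectionReport:
    """Score a matched list of target/prediction series into a report."""
    if len(targets_per_series) != len(preds_per_series):
        raise ValueError("need one prediction set per target set")
    raw = [match_errors(t, p, fs)
           for t, p in zip(targets_per_series, preds_per_series)]
    if remove_bias:
        centered, bias = remove_median_bias(raw)
    else:
        centered, bias = raw, {c: 0.0 for e in raw for c in e}
    classes = sorted({c for e in centered for c in e},
                     key=lambda c: (c not in targets_per_series[0].classes, c))
    total_samples = sum(t.n_samples for t in targets_per_series)

    errors: dict[str, list[np.ndarray]] = {}
    counts: dict[str, OutcomeCounts] = {}
    rate_map: dict[str, dict[str, float]] = {}
    mae_map: dict[str, dict[int, float]] = {}
    summaries: dict[str, dict[str, float]] = {}
    for cls in classes:
        vecs = [e.get(cls, np.array([])) for e in centered]
        n_pred = sum(p.counts().get(cls, 0) for p in preds_per_series)
        c = classify_outcomes(vecs, n_pred, total_samples, threshold_s)
        errors[cls] = vecs
        counts[cls] = c
        rate_map[cls] = rates(c)
        mae_map[cls], summaries[cls] = mae_per_series(vecs)
    return DetectionReport(
        classes=classes, errors=errors, counts=counts, rates=rate_map,
        mae=mae_map, mae_summary=summaries, fs=fs,
        total_samples=total_samples, threshold_s=threshold_s,
        median_bias_s=bias,
    )


def report_rows(report: DetectionReport) -> list[dict[str, float | str]]:
    """Flatten a report into one row per class (for tabular output)."""
    rows = []
    for cls in report.classes:
        c = report.counts[cls]
        r = report.rates[cls]
        s = report.mae_summary.get(cls, {})
        rows.append({
            "class": cls, "TP": c.TP, "FP": c.FP, "FN": c.FN, "TN": c.TN,
            "TPR": r["TPR"], "PPV": r["PPV"], "T1": r["T1"], "SPF": r["SPF"],
            "MAE_median_ms": 1e3 * s.get("median", math.nan),
            "MAE_mean_ms": 1e3 * s.get("mean", math.nan),
            "bias_ms": 1e3 * report.median_bias_s.get(cls, 0.0),
        })
    return rows
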