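"""Ridge-readout training with accumulated Gram matrices and tau estimation.

The readout solves ``Wout = YXt @ (XXt + gamma*I)^-1`` where ``XXt`` and
``YXt`` are accumulated per series (``XXt += X X^T``, ``YXt += Y X^T``)
so the concatenated state matrix is never materialized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, lstsq

from esngait.core_io import ESNConfig, ESNModel, EventTargets, TimeseriesRecord
from esngait.decoding import nrmse, nrmse_aggregate
from esngait.reservoir import StateMatrix, build_reservoir, readout, run_reservoir

logger = logging.getLogger(__name__)


@dataclass
class GramAccumulator:
    """Running sums of premultiplied state/target matrices.

    ``XXt`` is ``N x N`` symmetric PSD; ``YXt`` is ``Nout x N``.
    """

    N: int
    n_classes: int
    XXt: np.ndarray = field(init=False)
    YXt: np.ndarray = field(init=False)
    n_steps: int = 0
    n_series: int = 0

    def __post_init__(self) -> None:
        self.XXt = np.zeros((self.N, self.N))
        self.YXt = np.zeros((self.n_classes, self.N))


def trim_targets(targets: EventTargets, first_kept_index: int) -> EventTargets:
    """Restrict targets to the kept (post-transient) index range."""
    if not 0 <= first_kept_index < targets.n_samples:
        raise ValueError("first_kept_index out of range")
    idx = [i[i >= first_kept_index] - first_kept_index for i in targets.indices]
    return EventTargets(list(targets.classes), idx,
                        targets.n_samples - first_kept_index)


def accumulate(acc: GramAccumulator, states: StateMatrix,
               targets: EventTargets) -> GramAccumulator:
    """Absorb one series: ``XXt += X X^T`` and ``YXt += Y X^T``.

    ``targets`` must already be trimmed to the same kept index range as
    ``states`` (see :func:`trim_targets`).
    """
    if targets.n_classes != acc.n_classes:
        raise ValueError(f"expected {acc.n_classes} target classes, "
                         f"got {targets.n_classes}")
    if targets.n_samples != states.n_kept:
        raise ValueError("targets not trimmed to the kept state range")
    X = states.states
    acc.XXt += X @ X.T
    acc.YXt += targets.indicator @ X.T
    acc.n_steps += states.n_kept
    acc.n_series += 1
    return acc


def solve_readout(acc: GramAccumulator, gamma: float) -> np.ndarray:
    """Solve the regularized normal equations for the readout matrix.

    Uses a Cholesky solve on ``XXt + gamma*I`` (falls back to least squares
    if the system is not positive definite).
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    A = acc.XXt + gamma * np.eye(acc.N)
    try:
        c = cho_factor(A, lower=True)
        return cho_solve(c, acc.YXt.T).T
    except np.linalg.LinAlgError:
        pass
    if gamma == 0 and np.linalg.matrix_rank(A) < acc.N:
        raise np.linalg.LinAlgError("XXt is singular at gamma=0; use gamma > 0")
    sol, *_ = lstsq(A, acc.YXt.T)
    return sol.T


def estimate_tau(per_series_targets: list[EventTargets], fs: float) -> float:
    """Mean gait cycle duration in seconds.

    Per series the cycle duration is the 5th percentile (linear
    interpolation between order statistics) of successive HS gaps; the
    result is the arithmetic mean over series.
    """
    if not per_series_targets:
        raise ValueError("need at least one series")
    taus = []
    for k, tgt in enumerate(per_series_targets):
        hs = tgt.indices_for("HS")
        if hs.size < 2:
            raise ValueError(f"series {k}: need >= 2 HS events to estimate tau")
        gaps = np.diff(hs) / fs
        taus.append(float(np.percentile(gaps, 5)))
    return float(np.mean(taus))


def train(dataset: list[tuple[TimeseriesRecord, EventTargets]],
          cfg: ESNConfig | None = None,
          classes: list[str] | None = None) -> ESNModel:
    """Train an ESN on a list of (acceleration, targets) pairs.

    Builds the reservoir once, runs every series, accumulates the Gram
    matrices, solves the ridge readout and estimates tau from the HS gaps
    of the training targets.  All series must share sampling rate and
    channel count, and their targets must include the HS class.
    """
    cfg = cfg or ESNConfig()
    if not dataset:
        raise ValueError("dataset must be non-empty")
    fs = dataset[0][0].fs
    n_ch = dataset[0][0].n_channels
    for k, (rec, tgt) in enumerate(dataset):
        if rec.fs != fs:
            raise ValueError(f"series {k}: fs {rec.fs} != {fs}")
        if rec.n_channels != n_ch:
            raise ValueError(f"series {k}: {rec.n_channels} channels != {n_ch}")
        if rec.n_samples != tgt.n_samples:
            raise ValueError(f"series {k}: record/target length mismatch")
        if "HS" not in tgt.classes:
            raise ValueError(f"series {k}: targets must include HS (tau estimation)")
    if classes is None:
        classes = list(dataset[0][1].classes)
    for k, (_, tgt) in enumerate(dataset):
        if [c for c in tgt.classes if c in classes] != classes:
            raise ValueError(f"series {k}: target classes do not cover {classes}")

    Win, W = build_reservoir(cfg, n_ch)
    acc = GramAccumulator(cfg.N, len(classes))
    state_list: list[StateMatrix] = []
    target_list: list[EventTargets] = []
    for rec, tgt in dataset:
        states = run_reservoir(Win, W, rec, cfg.alpha, cfg.transient_s,
                               cfg.leak_variant)
        sub = EventTargets(list(classes),
                           [tgt.indices_for(c) for c in classes], tgt.n_samples)
        trimmed = trim_targets(sub, states.first_kept_index)
        accumulate(acc, states, trimmed)
        state_list.append(states)
        target_list.append(trimmed)

    Wout = solve_readout(acc, cfg.gamma)
    tau_s = estimate_tau([tgt for _, tgt in dataset], fs)
    model = ESNModel(config=cfg, Win=Win, W=W, Wout=Wout, tau_s=tau_s,
                     classes=list(classes))

    try:
        errors = [nrmse(readout(Wout, s), t.indicator)
                  for s, t in zip(state_list, target_list)]
        logger.info("training NRMSE = %.4f over %d series",
                    nrmse_aggregate(errors), len(errors))
    except ValueError:
        logger.info("training NRMSE unavailable (zero-variance target channel)")
    return model


def predict(model: ESNModel, rec: TimeseriesRecord) -> tuple[np.ndarray, int]:
    """Continuous readout for one record.

    Returns the ``(Nout, T_kept)`` prediction matrix and the index offset
    of its first column within the record (the transient cut).
    """
    if not model.is_trained:
        raise ValueError("model has no trained readout")
    states = run_reservoir(model.Win, model.W, rec, model.config.alpha,
                           model.config.transient_s, model.config.leak_variant)
    return readout(model.Wout, states), states.first_kept_index
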