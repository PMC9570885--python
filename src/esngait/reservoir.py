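"""Fixed random reservoir construction and leaky state updates.

The state recursion (0-based time index, bias prepended to the input) is::

    x~(n) = tanh(Win @ [1; u(n)] + W @ x(n-1))
    x(n)  = alpha * x~(n) + (1 - alpha) * x(n-1)

with ``x(-1) = 0`` and states during the transient (first ``transient_s``
seconds) discarded.  The ``(1 - alpha)`` retention coefficient is the
standard leaky-integrator form; a compatibility switch
(``leak_variant="printed"``) exposes the ``(alpha - 1)`` variant instead.

Per step the recursion costs ``N^2 + N*(Nin + Nout)`` multiply-adds plus
``O(N)`` work (tanh, leak mixing) — about ``N^2 + 14*N`` operations for
small channel counts; see :func:`per_step_operations`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from esngait.core_io import ESNConfig, TimeseriesRecord

logger = logging.getLogger(__name__)

_SPECTRAL_TOL = 1e-9


@dataclass
class StateMatrix:
    """Reservoir states with the transient removed.

    ``states`` has shape ``(N, T_kept)``; ``first_kept_index`` is the sample
    index (within the input record) of the first retained state.
    """

    states: np.ndarray
    first_kept_index: int
    fs: float

    @property
    def n_kept(self) -> int:
        return self.states.shape[1]


def _sparsify(rng: np.random.Generator, mat: np.ndarray, density: float) -> np.ndarray:
    """Zero a deterministic count round((1-density)*size) of uniformly chosen entries."""
    n_zero = int(round((1.0 - density) * mat.size))
    if n_zero > 0:
        flat = mat.ravel()
        flat[rng.choice(mat.size, size=n_zero, replace=False)] = 0.0
    return mat


def build_reservoir(cfg: ESNConfig, n_input_channels: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw the fixed input and recurrent matrices.

    ``W`` (N x N): uniform [-1, 1] entries, a fraction ``1 - P`` zeroed,
    rescaled so its largest-magnitude eigenvalue equals ``rho``.
    ``Win`` (N x (n_input_channels + 1)): uniform [-1, 1], fraction
    ``1 - Pi`` zeroed; the first (bias) column is scaled by ``Sb`` and the
    remaining columns by ``Si``.  Deterministic given ``cfg.seed``.
    """
    if n_input_channels < 1:
        raise ValueError("n_input_channels must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    N = cfg.N

    W = None
    for attempt in range(10):
        cand = _sparsify(rng, rng.uniform(-1.0, 1.0, size=(N, N)), cfg.P)
        radius = np.max(np.abs(np.linalg.eigvals(cand))) if cand.any() else 0.0
        if radius > _SPECTRAL_TOL:
            W = cand * (cfg.rho / radius)
            break
        logger.warning("reservoir draw %d has zero spectral radius; redrawing", attempt)
    if W is None:
        raise RuntimeError("could not draw a reservoir with nonzero spectral radius "
                           "(10 attempts); increase P or N")

    Win = _sparsify(rng, rng.uniform(-1.0, 1.0, size=(N, n_input_channels + 1)), cfg.Pi)
    Win[:, 0] *= cfg.Sb
    Win[:, 1:] *= cfg.Si
    return Win, W


def run_reservoir(Win: np.ndarray, W: np.ndarray, u: TimeseriesRecord,
                  alpha: float, transient_s: float = 1.25,
                  leak_variant: str = "standard",
                  x0: np.ndarray | None = None) -> StateMatrix:
    """Run the leaky state recursion over one record and drop the transient.

    ``x0`` overrides the zero initial state (used for echo-state checks).
    """
    Win = np.asarray(Win, dtype=float)
    W = np.asarray(W, dtype=float)
    N = W.shape[0]
    if Win.shape[0] != N:
        raise ValueError("Win and W row counts differ")
    if Win.shape[1] != u.n_channels + 1:
        raise ValueError(f"Win expects {Win.shape[1] - 1} input channels, "
                         f"record has {u.n_channels}")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if leak_variant not in ("standard", "printed"):
        raise ValueError("leak_variant must be 'standard' or 'printed'")
    T = u.n_samples
    n_transient = int(round(transient_s * u.fs))
    if T <= n_transient:
        raise ValueError(f"record too short: T={T} <= transient of {n_transient} "
                         f"samples; need at least {n_transient + 1}")

    retain = (1.0 - alpha) if leak_variant == "standard" else (alpha - 1.0)
    inp = np.vstack([np.ones((1, T)), u.data])
    drive = Win @ inp  # precomputed input drive for every step
    x = np.zeros(N) if x0 is None else np.asarray(x0, dtype=float).copy()
    states = np.empty((N, T - n_transient))
    for n in range(T):
        x = alpha * np.tanh(drive[:, n] + W @ x) + retain * x
        if n >= n_transient:
            states[:, n - n_transient] = x
    return StateMatrix(states, n_transient, u.fs)


def readout(Wout: np.ndarray, states: StateMatrix) -> np.ndarray:
    """Linear readout: plain matrix product ``Wout @ states`` (Nout x T_kept)."""
    Wout = np.atleast_2d(np.asarray(Wout, dtype=float))
    if Wout.shape[1] != states.states.shape[0]:
        raise ValueError(f"Wout has {Wout.shape[1]} columns, states have "
                         f"{states.states.shape[0]} rows")
    return Wout @ states.states


def per_step_operations(N: int, n_input_channels: int, n_output_classes: int) -> int:
    """Multiply-add count of one state update plus readout step.

    ``N^2`` (recurrent matvec) + ``N*Nin`` (input drive, bias included)
    + ``N*Nout`` (readout) + ``3N`` (tanh evaluation and leak mixing).
    For ``Nin <= 5`` and ``Nout <= 6`` this is at most ``N^2 + 14*N``.
    """
    n_in = n_input_channels + 1
    return N * N + N * n_in + N * n_output_classes + 3 * N
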