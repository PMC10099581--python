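"""Discretised master-equation engine.

The master equation propagates a utilisation distribution (UD) one fix
interval forward by integrating the movement kernel against the current
UD.  On a raster it becomes a stochastic-matrix product

    U(s, t + tau) = sum_{s'} P_tau(s | s', t) U(s', t)

with columns of P indexed by source cells, so propagation is a plain
matrix-vector product.  Steady states solve U* = P U*, found either by
power iteration or directly from the leading eigenvector.

Grid-shaped UDs are flattened in C order (row 0 = bottom row of the grid).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .kernel import KernelSpec, evaluate_kernel
from .landscape import RasterLayer, StudyArea

__all__ = [
    "UD",
    "TransitionMatrix",
    "build_transition_matrix",
    "propagate",
    "cumulative_ud",
    "steady_state_fixed_point",
    "steady_state_eigen",
    "SteadyStateResult",
]


@dataclass
class UD:
    """A probability distribution over grid cells at one time step."""

    probabilities: np.ndarray  # grid-shaped
    time: float = 0.0

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if np.any(self.probabilities < -1e-12):
            raise ValueError("UD has negative entries")
        s = self.probabilities.sum()
        if abs(s - 1.0) > 1e-10:
            raise ValueError(f"UD must sum to 1, got {s!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.probabilities.shape

    def flat(self) -> np.ndarray:
        return self.probabilities.ravel()

    @classmethod
    def uniform(cls, area: StudyArea, time: float = 0.0) -> "UD":
        p = area.admissible.astype(float)
        return cls(p / p.sum(), time)

    @classmethod
    def point_mass(cls, area: StudyArea, x: float, y: float, time: float = 0.0) -> "UD":
        p = np.zeros(area.shape)
        i, j = area.cell_of(x, y)
        p[i, j] = 1.0
        return cls(p, time)

    def as_layer(self, area: StudyArea, name: str = "ud") -> RasterLayer:
        return RasterLayer(self.probabilities, area.cell_size, area.origin, name)


@dataclass
class TransitionMatrix:
    """Column-stochastic transition matrix P[s, s'] over flattened grid cells."""

    matrix: np.ndarray | sp.spmatrix
    grid_shape: tuple[int, int]
    time: float | str = "static"

    def __post_init__(self) -> None:
        n = self.grid_shape[0] * self.grid_shape[1]
        if self.matrix.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match grid "
                f"{self.grid_shape} ({n} cells)"
            )
        colsums = np.asarray(self.matrix.sum(axis=0)).ravel()
        if np.max(np.abs(colsums - 1.0)) > 1e-10:
            raise ValueError("transition matrix columns must sum to 1")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    def apply(self, u_flat: np.ndarray) -> np.ndarray:
        return np.asarray(self.matrix @ u_flat).ravel()


def build_transition_matrix(
    spec: KernelSpec,
    t: float = 0.0,
    sparse: bool = False,
    sparse_threshold: float = 1e-12,
) -> TransitionMatrix:
    """Assemble P_tau(s | s', t): column s' is the kernel from cell s'.

    Requires kappa = 0 (no turn-angle component); a bearing-indexed state
    space is not supported by this engine — use the individual-based
    simulation in :mod:`stepscale.ibm` for correlated movement.

    ``sparse=True`` stores the matrix in CSC form, dropping entries below
    ``sparse_threshold`` and renormalising columns; recommended above
    ~10^4 cells.
    """
    if spec.selection_free.kappa > 0:
        raise ValueError(
            "transition matrices require kappa = 0; correlated movement "
            "is supported only by the individual-based model (stepscale.ibm)"
        )
    area = spec.study_area
    n = area.n_cells
    cols = []
    for idx in range(n):
        i, j = divmod(idx, area.n_cols)
        if not area.admissible[i, j]:
            col = np.zeros(n)
            col[idx] = 1.0  # inadmissible sources are absorbing placeholders
        else:
            col = evaluate_kernel(spec, area.centre_of(i, j), None, t).ravel()
        cols.append(col)
    P = np.column_stack(cols)
    if sparse:
        P[P < sparse_threshold] = 0.0
        P = P / P.sum(axis=0, keepdims=True)
        P = sp.csc_matrix(P)
    return TransitionMatrix(P, area.shape, time=t if not spec.is_static() else "static")


def propagate(
    u0: UD,
    matrices: TransitionMatrix | Callable[[float], TransitionMatrix],
    n_steps: int,
    tau: float = 1.0,
) -> list[UD]:
    """Propagate a UD forward ``n_steps`` fix intervals.

    ``matrices`` is either one static transition matrix or a callable
    ``t -> TransitionMatrix`` rebuilt at each step (time-varying kernels).
    Returns the full sequence [u0, u1, ..., u_{n_steps}].  Probability
    mass is renormalised against accumulated round-off each step (drift
    is at the 1e-15 level per step; the contract is conservation to 1e-9).
    """
    if n_steps < 0:
        raise ValueError("n_steps must be non-negative")
    static = isinstance(matrices, TransitionMatrix)
    out = [u0]
    u = u0.flat().copy()
    t = u0.time
    for _ in range(n_steps):
        P = matrices if static else matrices(t)
        if P.grid_shape != u0.shape:
            raise ValueError(
                f"grid mismatch: UD {u0.shape} vs matrix {P.grid_shape}"
            )
        u = P.apply(u)
        u = u / u.sum()
        t = t + tau
        out.append(UD(u.reshape(u0.shape), time=t))
    return out


def cumulative_ud(uds: Sequence[UD]) -> UD:
    """Time-averaged (cumulative) UD over a sequence of snapshots.

    This is the discrete analogue of the cumulative space-use measure
    (1/t) * integral_0^t u(x, t') dt' that trajectory-based estimators
    report; it coincides with the steady state only once the UD has
    converged.
    """
    if len(uds) == 0:
        raise ValueError("cumulative_ud of an empty sequence")
    shape = uds[0].shape
    acc = np.zeros(shape)
    for u in uds:
        if u.shape != shape:
            raise ValueError("all UDs must share one grid")
        acc += u.probabilities
    acc /= acc.sum()
    return UD(acc, time=uds[-1].time)


@dataclass
class SteadyStateResult:
    """Steady-state solve outcome: the UD plus convergence diagnostics."""

    ud: UD
    converged: bool
    n_iterations: int
    residual: float
    degenerate: bool = False

    def __iter__(self):  # allow ud, converged = result-style unpacking
        yield self.ud
        yield self.converged


def steady_state_fixed_point(
    P: TransitionMatrix,
    tol: float = 1e-10,
    max_iter: int = 1_000_000,
    u_init: UD | None = None,
) -> SteadyStateResult:
    """Power iteration for the steady state U* = P U*.

    Iterates u <- P u from ``u_init`` (uniform by default) until the L1
    residual ||P u - u||_1 drops below ``tol``.  If ``max_iter`` is
    reached the best iterate is returned flagged non-converged — the UD
    may genuinely oscillate rather than settle.
    """
    if P.time != "static":
        raise ValueError("steady states require a time-invariant kernel")
    n = P.n_cells
    u = (
        u_init.flat().copy()
        if u_init is not None
        else np.full(n, 1.0 / n)
    )
    if u_init is not None and u_init.shape != P.grid_shape:
        raise ValueError("u_init grid does not match the matrix")
    residual = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        nxt = P.apply(u)
        nxt = nxt / nxt.sum()
        residual = float(np.abs(nxt - u).sum())
        u = nxt
        if residual < tol:
            break
    converged = residual < tol
    if not converged:
        warnings.warn(
            f"power iteration stopped after {it} iterations with L1 "
            f"residual {residual:.3e}; the UD may be oscillatory",
            stacklevel=2,
        )
    return SteadyStateResult(
        UD(u.reshape(P.grid_shape)), converged, it, residual
    )


def steady_state_eigen(P: TransitionMatrix) -> SteadyStateResult:
    """Steady state from the leading eigenvector (eigenvalue 1) of P.

    Degenerate multiplicity of the unit eigenvalue (a disconnected chain)
    is reported via the ``degenerate`` flag and a warning; the first
    eigenvector is returned.
    """
    if P.time != "static":
        raise ValueError("steady states require a time-invariant kernel")
    M = P.matrix
    if sp.issparse(M):
        vals, vecs = spla.eigs(M.astype(float), k=min(4, M.shape[0] - 2), which="LR")
    else:
        vals, vecs = np.linalg.eig(np.asarray(M))
    order = np.argsort(-vals.real)
    vals, vecs = vals[order], vecs[:, order]
    unit = np.abs(vals - 1.0) < 1e-8
    degenerate = int(unit.sum()) > 1
    if degenerate:
        warnings.warn(
            f"eigenvalue 1 has multiplicity {int(unit.sum())} (disconnected "
            "chain); returning the first stationary eigenvector",
            stacklevel=2,
        )
    v = vecs[:, 0].real
    if v.sum() < 0:
        v = -v
    if np.any(v < -1e-12 * max(1.0, np.abs(v).max())):
        warnings.warn("leading eigenvector has negative entries; clipping", stacklevel=2)
    v = np.clip(v, 0.0, None)
    v = v / v.sum()
    residual = float(np.abs(P.apply(v) - v).sum())
    return SteadyStateResult(
        UD(v.reshape(P.grid_shape)), True, 0, residual, degenerate=degenerate
    )
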