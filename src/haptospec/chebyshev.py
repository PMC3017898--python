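"""Chebyshev collocation primitives on the unit tissue domain.

Space is discretised on Chebyshev--Gauss--Lobatto (CGL) nodes mapped to
[0, 1], with a dense first-order differentiation matrix ``D``.  Second
derivatives are never built directly: they arise by composing first-order
operators whose boundary rows have been overwritten so that the flux
boundary conditions of the invasion models are embedded in the
semidiscrete system.  This module builds the grid, ``D`` and all derived
boundary-modified operators.

Notation (``N`` is the spectral order, giving ``N + 2`` nodes indexed
``0 .. N+1`` with ``x_0 = 0`` and ``x_{N+1} = 1``):

``D1``
    the upper-left ``(N+1) x (N+1)`` block of ``D`` (rows/columns
    ``0..N``), used when the value at the right end is pinned.
``D0``
    ``D1`` with its first row zeroed — the row where the left no-flux
    condition supplies the derivative instead.
``D00``
    the full ``(N+2) x (N+2)`` matrix with first *and* last rows zeroed,
    for no-flux conditions at both walls.
``w``
    the last column of ``D`` restricted to rows ``0..N``; it carries the
    contribution of the known right-end value into the interior rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt

__all__ = [
    "CollocationGrid",
    "BoundaryOperators",
    "cgl_points",
    "differentiation_matrix",
    "boundary_operators",
    "boundary_sum",
]


def cgl_points(N: int) -> npt.NDArray[np.float64]:
    """Chebyshev–Gauss–Lobatto nodes on [0, 1], ascending.

    Returns the ``N + 2`` points ``x_i = 1/2 - (1/2) cos(i pi / (N+1))``
    for ``i = 0 .. N+1``, so that ``x_0 = 0`` and ``x_{N+1} = 1``.

    Parameters
    ----------
    N : int
        Spectral order; must be >= 1.
    """
    if not isinstance(N, (int, np.integer)) or isinstance(N, bool):
        raise TypeError(f"N must be an integer, got {type(N).__name__}")
    if N < 1:
        raise ValueError(f"spectral order N must be >= 1, got {N}")
    i = np.arange(N + 2)
    x = 0.5 - 0.5 * np.cos(i * np.pi / (N + 1))
    # pin the endpoints exactly; cos rounding can leave ~1e-17 residue
    x[0] = 0.0
    x[-1] = 1.0
    return x


def differentiation_matrix(nodes: npt.NDArray[np.float64]) -> npt.NDArray[np.float64]:
    """First-order polynomial differentiation matrix on arbitrary distinct nodes.

    ``D @ p(nodes)`` equals the derivative of the degree ``len(nodes)-1``
    interpolating polynomial of ``p`` at the nodes.  Off-diagonal entries
    use the barycentric form ``d_ij = (w_j / w_i) / (x_i - x_j)``; each
    diagonal entry is the negated sum of its row's off-diagonal entries
    ("negative-sum trick"), which makes constants differentiate to zero
    exactly and is the best-conditioned standard construction.
    """
    x = np.asarray(nodes, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("nodes must be a 1-D array with at least two entries")
    diff = x[:, None] - x[None, :]
    off = ~np.eye(x.size, dtype=bool)
    if np.any(diff[off] == 0.0):
        raise ValueError("nodes must be pairwise distinct")
    np.fill_diagonal(diff, 1.0)
    # barycentric weights; the factor 4/span keeps the products O(1)
    span = x.max() - x.min()
    bw = 1.0 / np.prod(diff * (4.0 / span), axis=1)
    D = (bw[None, :] / bw[:, None]) / diff
    np.fill_diagonal(D, 0.0)
    np.fill_diagonal(D, -D.sum(axis=1))
    return D


@dataclass(frozen=True)
class CollocationGrid:
    """CGL collocation grid on [0, 1] with its differentiation matrix."""

    N: int
    nodes: npt.NDArray[np.float64] = field(repr=False)
    D: npt.NDArray[np.float64] = field(repr=False)

    @classmethod
    def from_order(cls, N: int) -> "CollocationGrid":
        nodes = cgl_points(N)
        return cls(N=int(N), nodes=nodes, D=differentiation_matrix(nodes))

    @property
    def n_nodes(self) -> int:
        return self.N + 2


@dataclass(frozen=True)
class BoundaryOperators:
    """Boundary-modified differentiation operators derived from a grid.

    ``row0`` and ``row_last`` are rows 0 and N+1 of the full matrix; dotted
    with a full-length nodal vector they give the interpolant's derivative
    at the walls (the sums ``s_0`` and ``s_{N+1}`` of the scheme).
    """

    D: npt.NDArray[np.float64] = field(repr=False)
    D1: npt.NDArray[np.float64] = field(repr=False)
    D0: npt.NDArray[np.float64] = field(repr=False)
    D00: npt.NDArray[np.float64] = field(repr=False)
    w: npt.NDArray[np.float64] = field(repr=False)
    e1: npt.NDArray[np.float64] = field(repr=False)
    row0: npt.NDArray[np.float64] = field(repr=False)
    row_last: npt.NDArray[np.float64] = field(repr=False)

    @classmethod
    def from_grid(cls, grid: CollocationGrid) -> "BoundaryOperators":
        D = grid.D
        n = grid.N + 2
        D1 = D[: n - 1, : n - 1].copy()
        D0 = D1.copy()
        D0[0, :] = 0.0
        D00 = D.copy()
        D00[0, :] = 0.0
        D00[-1, :] = 0.0
        w = D[: n - 1, n - 1].copy()
        e1 = np.zeros(n - 1)
        e1[0] = 1.0
        return cls(
            D=D.copy(),
            D1=D1,
            D0=D0,
            D00=D00,
            w=w,
            e1=e1,
            row0=D[0, :].copy(),
            row_last=D[-1, :].copy(),
        )


def boundary_operators(grid: CollocationGrid) -> BoundaryOperators:
    """Build all boundary-modified operators for ``grid``."""
    return BoundaryOperators.from_grid(grid)


def boundary_sum(row: npt.NDArray[np.float64], values: npt.NDArray[np.float64]) -> float:
    """Dot a boundary row of D with a full-length nodal vector.

    This is the sum ``s = sum_j d_{row,j} v_j`` through which the wall
    derivative of a field enters the boundary-embedded scheme.
    """
    row = np.asarray(row, dtype=float)
    values = np.asarray(values, dtype=float)
    if row.shape != values.shape or row.ndim != 1:
        raise ValueError(
            f"row and values must be 1-D of equal length, got {row.shape} vs {values.shape}"
        )
    return float(row @ values)
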