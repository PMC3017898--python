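"""Invasion model variants and their semidiscrete right-hand sides.

Four one-dimensional continuum models of tumour invasion are supported,
all built from tumour cell density ``n``, extracellular matrix (ECM)
density ``f`` and matrix-degradative enzyme (MDE) concentration ``m`` on
the scaled tissue domain [0, 1]:

``BASIC_DIRICHLET``
    random motility + haptotaxis for n, ECM degradation ``-eta*m*f``,
    MDE diffusion/production/decay; no-flux wall at x=0 and tumour/MDE
    pinned to zero at x=1 (the tissue far from the initial tumour).
``PROLIFERATION``
    adds logistic tumour proliferation ``mu1*n*(1-n-f)`` and ECM renewal
    ``mu2*f*(1-n-f)``; no-flux walls at both ends.
``SATURATING_MDE``
    as PROLIFERATION but MDE production saturates: ``alpha*n*(1-n)``
    instead of ``alpha*n`` (polarised expression at the invading edge).
``INHIBITOR``
    four fields: adds endogenous inhibitors ``u`` produced by the ECM
    (``xi*f``), neutralising MDEs (``theta*u*m``) and decaying
    (``rho*u``); no-flux walls for n, m, u.

The haptotactic flux is ``-gamma * n * df/dx``: cells climb ECM
gradients.  Spatial derivatives are replaced by the collocation operators
of :mod:`haptospec.chebyshev`; the no-flux conditions
``dn*n_x - gamma*n*f_x = 0`` and ``m_x = u_x = 0`` are embedded in the
operators by substituting the wall derivative implied by the boundary
condition for the spectral one, so the semidiscrete flux vanishes at the
wall nodes identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import numpy.typing as npt

from .chebyshev import BoundaryOperators, CollocationGrid, boundary_sum

__all__ = [
    "ModelVariant",
    "InvasionParameters",
    "StateVector",
    "initial_state",
    "mde_production",
    "haptotaxis_divergence",
    "rhs_basic",
    "rhs_zero_flux",
    "rhs",
]


class ModelVariant(str, Enum):
    """Which invasion model (and hence boundary treatment) to solve."""

    BASIC_DIRICHLET = "basic"
    PROLIFERATION = "proliferation"
    SATURATING_MDE = "saturating"
    INHIBITOR = "inhibitor"

    @property
    def has_inhibitor(self) -> bool:
        return self is ModelVariant.INHIBITOR

    @property
    def zero_flux_right(self) -> bool:
        """True when the right wall is no-flux rather than Dirichlet."""
        return self is not ModelVariant.BASIC_DIRICHLET

    @property
    def n_fields(self) -> int:
        return 4 if self.has_inhibitor else 3


@dataclass(frozen=True)
class InvasionParameters:
    """Coefficients of the invasion models (dimensionless, scaled domain).

    Parameters
    ----------
    dn, dm, du : float
        Random-motility / diffusion coefficients of tumour cells, MDEs
        and inhibitors.  ``dn`` and ``dm`` must be positive; ``du`` only
        matters (and must be positive) for the INHIBITOR variant.
    gamma : float
        Haptotaxis coefficient.
    eta : float
        ECM degradation rate by MDEs.
    alpha, beta : float
        MDE production and decay rates.
    mu1, mu2 : float
        Tumour proliferation and ECM renewal rates.
    theta, xi, rho : float
        MDE–inhibitor neutralisation, inhibitor production and inhibitor
        decay rates (INHIBITOR variant).
    epsilon : float
        Width of the initial tumour, ``n(x,0) = exp(-x^2/epsilon)``.
    """

    dn: float = 0.001
    dm: float = 0.001
    du: float = 0.0
    gamma: float = 0.005
    eta: float = 10.0
    alpha: float = 0.1
    beta: float = 0.0
    mu1: float = 0.0
    mu2: float = 0.0
    theta: float = 0.0
    xi: float = 0.0
    rho: float = 0.0
    epsilon: float = 0.01

    def __post_init__(self) -> None:
        for name in (
            "dn", "dm", "du", "gamma", "eta", "alpha", "beta",
            "mu1", "mu2", "theta", "xi", "rho", "epsilon",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"parameter {name} must be finite and >= 0, got {v}")
        if self.dn <= 0:
            raise ValueError("tumour motility dn must be positive")
        if self.dm <= 0:
            raise ValueError("MDE diffusion dm must be positive")
        if self.epsilon <= 0:
            raise ValueError("initial tumour width epsilon must be positive")

    def validate_for(self, variant: ModelVariant) -> None:
        if variant.has_inhibitor and self.du <= 0:
            raise ValueError("inhibitor diffusion du must be positive for the INHIBITOR variant")

    def evolve(self, **changes: float) -> "InvasionParameters":
        """Return a copy with the given coefficients replaced."""
        return replace(self, **changes)


@dataclass
class StateVector:
    """Nodal values of the fields, in the variant's layout.

    For zero-flux variants every field spans all ``N + 2`` nodes.  For
    BASIC_DIRICHLET, ``n`` and ``m`` span nodes ``0..N`` (the value at
    node ``N+1`` is pinned to 0 by the Dirichlet condition) and ``f``
    spans nodes ``0..N`` with the constant value at the right wall kept
    in ``f_end``: since ``m`` vanishes there, the ECM is never degraded
    at that wall and ``f(1, t) = f(1, 0)`` for all t.
    """

    variant: ModelVariant
    n: npt.NDArray[np.float64]
    f: npt.NDArray[np.float64]
    m: npt.NDArray[np.float64]
    u: npt.NDArray[np.float64] | None = None
    f_end: float | None = None

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        self.m = np.asarray(self.m, dtype=float)
        if self.u is not None:
            self.u = np.asarray(self.u, dtype=float)
        if self.variant.has_inhibitor and self.u is None:
            raise ValueError("INHIBITOR variant requires an inhibitor field u")
        if not self.variant.has_inhibitor and self.u is not None:
            raise ValueError(f"variant {self.variant.value} carries no inhibitor field")
        if self.variant is ModelVariant.BASIC_DIRICHLET and self.f_end is None:
            raise ValueError("BASIC_DIRICHLET requires the stored wall value f_end")
        if not (self.n.shape == self.f.shape == self.m.shape):
            raise ValueError("fields n, f, m must have equal length")
        if self.u is not None and self.u.shape != self.n.shape:
            raise ValueError("inhibitor field u must match the other fields in length")

    def check_layout(self, grid: CollocationGrid) -> None:
        expected = grid.N + 1 if self.variant is ModelVariant.BASIC_DIRICHLET else grid.N + 2
        if self.n.size != expected:
            raise ValueError(
                f"{self.variant.value} state must have {expected} nodal values per field, "
                f"got {self.n.size}"
            )

    # --- flat-array packing for the ODE integrator -------------------------

    def to_array(self) -> npt.NDArray[np.float64]:
        parts = [self.n, self.f, self.m]
        if self.u is not None:
            parts.append(self.u)
        return np.concatenate(parts)

    @classmethod
    def from_array(
        cls,
        y: npt.NDArray[np.float64],
        variant: ModelVariant,
        f_end: float | None = None,
    ) -> "StateVector":
        k = variant.n_fields
        if y.size % k:
            raise ValueError(f"flat state of length {y.size} is not divisible into {k} fields")
        blocks = np.split(np.asarray(y, dtype=float), k)
        u = blocks[3] if variant.has_inhibitor else None
        return cls(variant=variant, n=blocks[0], f=blocks[1], m=blocks[2], u=u, f_end=f_end)

    # --- full-grid views ---------------------------------------------------

    def full_fields(self) -> dict[str, npt.NDArray[np.float64]]:
        """Fields on all N+2 nodes, appending the pinned Dirichlet values."""
        if self.variant is ModelVariant.BASIC_DIRICHLET:
            out = {
                "n": np.append(self.n, 0.0),
                "f": np.append(self.f, self.f_end),
                "m": np.append(self.m, 0.0),
            }
        else:
            out = {"n": self.n.copy(), "f": self.f.copy(), "m": self.m.copy()}
            if self.u is not None:
                out["u"] = self.u.copy()
        return out


def initial_state(
    grid: CollocationGrid, params: InvasionParameters, variant: ModelVariant
) -> StateVector:
    """Closed-form initial condition on the collocation nodes.

    The tumour starts as a Gaussian centred at the left wall,
    ``n(x,0) = exp(-x^2/epsilon)``; MDEs are proportional to the tumour
    with constant 1/2, ``m(x,0) = n(x,0)/2``, and the ECM has already
    been partially degraded, ``f(x,0) = 1 - n(x,0)/2``.  Inhibitors start
    at zero.
    """
    params.validate_for(variant)
    x = grid.nodes
    n0 = np.exp(-(x**2) / params.epsilon)
    f0 = 1.0 - 0.5 * n0
    m0 = 0.5 * n0
    if variant is ModelVariant.BASIC_DIRICHLET:
        return StateVector(
            variant=variant, n=n0[:-1], f=f0[:-1], m=m0[:-1], f_end=float(f0[-1])
        )
    u0 = np.zeros_like(n0) if variant.has_inhibitor else None
    return StateVector(variant=variant, n=n0, f=f0, m=m0, u=u0)


def mde_production(
    n: npt.NDArray[np.float64], variant: ModelVariant, alpha: float
) -> npt.NDArray[np.float64]:
    """MDE production law: ``alpha*n``, saturating to ``alpha*n*(1-n)``.

    The saturating form (SATURATING_MDE) models polarised MDE expression
    at the invading edge: crowded regions (n near 1) stop producing.
    """
    n = np.asarray(n, dtype=float)
    if variant is ModelVariant.SATURATING_MDE:
        return alpha * n * (1.0 - n)
    return alpha * n


def haptotaxis_divergence(
    n: npt.NDArray[np.float64],
    f: npt.NDArray[np.float64],
    ops: BoundaryOperators,
) -> npt.NDArray[np.float64]:
    """Discrete ``d/dx (n df/dx)`` on the full grid (zero-flux convention).

    The ECM obeys no boundary condition, so its gradient is taken with the
    unmodified full differentiation matrix; the outer derivative likewise.
    """
    n = np.asarray(n, dtype=float)
    f = np.asarray(f, dtype=float)
    size = ops.D.shape[0]
    if n.shape != (size,) or f.shape != (size,):
        raise ValueError(f"n and f must be full-length vectors of size {size}")
    fx = ops.D @ f
    return ops.D @ (n * fx)


def rhs_basic(
    state: StateVector,
    grid: CollocationGrid,
    ops: BoundaryOperators,
    params: InvasionParameters,
) -> StateVector:
    """Semidiscrete RHS for the basic model (no-flux left, Dirichlet right).

    The unknowns are the nodal values at nodes 0..N (3N+3 ODEs); the values
    at node N+1 are supplied by the Dirichlet condition (n = m = 0, f held
    at its initial wall value) wherever full-length vectors are needed in
    the boundary sums.
    """
    if state.variant is not ModelVariant.BASIC_DIRICHLET:
        raise ValueError(f"rhs_basic got variant {state.variant.value}")
    state.check_layout(grid)
    p = params
    n, f, m, f_end = state.n, state.f, state.m, state.f_end

    n_full = np.append(n, 0.0)
    f_full = np.append(f, f_end)
    m_full = np.append(m, 0.0)
    s0f = boundary_sum(ops.row0, f_full)
    sN1n = boundary_sum(ops.row_last, n_full)
    sN1f = boundary_sum(ops.row_last, f_full)
    sN1m = boundary_sum(ops.row_last, m_full)

    # wall-substituted first derivative of n: row 0 comes from the no-flux
    # condition n_x(0) = (gamma/dn) n(0) f_x(0)
    nx = ops.D0 @ n + (p.gamma / p.dn) * n[0] * s0f * ops.e1
    fx = ops.D1 @ f + f_end * ops.w
    fxx = ops.D1 @ fx + sN1f * ops.w

    dn_dt = p.dn * (ops.D1 @ nx + sN1n * ops.w) - p.gamma * (nx * fx + n * fxx)
    df_dt = -p.eta * m * f
    dm_dt = p.dm * (ops.D1 @ (ops.D0 @ m) + sN1m * ops.w) + p.alpha * n - p.beta * m
    return StateVector(
        variant=state.variant, n=dn_dt, f=df_dt, m=dm_dt, f_end=0.0
    )


def rhs_zero_flux(
    state: StateVector,
    grid: CollocationGrid,
    ops: BoundaryOperators,
    params: InvasionParameters,
) -> StateVector:
    """Semidiscrete RHS for the no-flux variants (all N+2 nodes evolve).

    The tumour flux ``dn*n_x - gamma*n*f_x`` is assembled with the wall
    rows of ``n_x`` substituted from the boundary condition, which makes
    the discrete flux vanish identically at both wall nodes; the outer
    derivative is the full matrix.  Second derivatives of m (and u) are
    the composition ``D @ (D00 @ .)`` — the boundary-zeroed first
    derivative (enforcing ``m_x = 0`` at the walls) differentiated once
    more.
    """
    variant = state.variant
    if not variant.zero_flux_right:
        raise ValueError(f"rhs_zero_flux got variant {variant.value}")
    state.check_layout(grid)
    params.validate_for(variant)
    p = params
    n, f, m = state.n, state.f, state.m

    s0f = boundary_sum(ops.row0, f)
    sN1f = boundary_sum(ops.row_last, f)
    w_bc = np.zeros(grid.N + 2)
    w_bc[0] = s0f * n[0]
    w_bc[-1] = sN1f * n[-1]

    fx = ops.D @ f
    # dn * nx with the wall rows substituted; flux is zero at nodes 0, N+1
    flux = p.dn * (ops.D00 @ n) + p.gamma * w_bc - p.gamma * n * fx
    dn_dt = ops.D @ flux + p.mu1 * n * (1.0 - n - f)
    df_dt = -p.eta * m * f + p.mu2 * f * (1.0 - n - f)
    dm_dt = p.dm * (ops.D @ (ops.D00 @ m)) + mde_production(n, variant, p.alpha) - p.beta * m

    du_dt = None
    if variant.has_inhibitor:
        u = state.u
        dm_dt = dm_dt - p.theta * u * m
        du_dt = p.du * (ops.D @ (ops.D00 @ u)) + p.xi * f - p.theta * u * m - p.rho * u
    return StateVector(variant=variant, n=dn_dt, f=df_dt, m=dm_dt, u=du_dt)


def rhs(
    state: StateVector,
    grid: CollocationGrid,
    ops: BoundaryOperators,
    params: InvasionParameters,
) -> StateVector:
    """Dispatch to the variant's right-hand side."""
    if state.variant is ModelVariant.BASIC_DIRICHLET:
        return rhs_basic(state, grid, ops, params)
    return rhs_zero_flux(state, grid, ops, params)
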