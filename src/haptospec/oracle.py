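"""Independent finite-difference reference solver and diagnostics.

This module deliberately shares no discretisation code with the spectral
solver: the PDEs are rediscretised from scratch on a uniform grid with a
second-order conservative finite-volume scheme, and integrated with the
same stiff-integrator contract.  Agreement between the two routes on a
refinement study is the main correctness evidence for both.

Also provided: barycentric evaluation of the spectral interpolant,
Clenshaw–Curtis quadrature on the collocation nodes (total mass), and a
peak/dip rule that counts "clusters" of tumour cells — secondary local
maxima at the invading edge, detached from the main tumour body by a
pronounced dip, the hallmark of metastatic break-off in these models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt
from scipy import sparse
from scipy.integrate import solve_ivp

from .chebyshev import CollocationGrid
from .integrate import IntegrationError, IntegratorSettings, SimulationResult
from .models import InvasionParameters, ModelVariant, mde_production

__all__ = [
    "UniformGridResult",
    "fd_reference_solve",
    "fd_rhs",
    "barycentric_interpolate",
    "clenshaw_curtis_weights",
    "total_mass",
    "count_clusters",
    "compare_solutions",
]


@dataclass
class UniformGridResult:
    """Finite-difference snapshots on a uniform grid of M points on [0, 1]."""

    variant: ModelVariant
    params: InvasionParameters
    M: int
    x: npt.NDArray[np.float64]
    times: npt.NDArray[np.float64]
    fields: dict[str, npt.NDArray[np.float64]] = field(repr=False)

    def snapshot(self, time: float, name: str) -> npt.NDArray[np.float64]:
        idx = np.flatnonzero(np.isclose(self.times, time, rtol=0.0, atol=1e-12))
        if idx.size == 0:
            raise KeyError(f"time {time} not among snapshots {self.times.tolist()}")
        return self.fields[name][idx[0]]


def _field_names(variant: ModelVariant) -> list[str]:
    return ["n", "f", "m", "u"] if variant.has_inhibitor else ["n", "f", "m"]


def fd_rhs(
    variant: ModelVariant,
    params: InvasionParameters,
    x: npt.NDArray[np.float64],
    fields: dict[str, npt.NDArray[np.float64]],
) -> dict[str, npt.NDArray[np.float64]]:
    """Finite-volume evaluation of the PDE right-hand sides on a uniform grid.

    Diffusive and haptotactic fluxes are formed at the cell faces
    (arithmetic-mean n, centred gradients); each node owns a cell, the
    wall nodes half-cells, and the wall fluxes are those the boundary
    conditions prescribe (zero for no-flux walls).  This makes the
    trapezoid mass of n exactly conserved for no-flux runs.  For the
    Dirichlet variant the pinned values n = m = 0 at x = 1 have zero time
    derivative.
    """
    p = params
    h = float(x[1] - x[0])
    n, f, m = fields["n"], fields["f"], fields["m"]
    out: dict[str, npt.NDArray[np.float64]] = {}

    # tumour flux at interior faces: dn*n_x - gamma*n*f_x
    dn_face = np.diff(n) / h
    df_face = np.diff(f) / h
    n_face = 0.5 * (n[:-1] + n[1:])
    flux = p.dn * dn_face - p.gamma * n_face * df_face

    dn_dt = np.empty_like(n)
    dn_dt[1:-1] = np.diff(flux) / h
    dn_dt[0] = flux[0] / (0.5 * h)          # wall flux = 0 (no-flux BC)
    dn_dt[-1] = -flux[-1] / (0.5 * h)
    dn_dt += p.mu1 * n * (1.0 - n - f)

    df_dt = -p.eta * m * f + p.mu2 * f * (1.0 - n - f)

    g_face = p.dm * np.diff(m) / h
    dm_dt = np.empty_like(m)
    dm_dt[1:-1] = np.diff(g_face) / h
    dm_dt[0] = g_face[0] / (0.5 * h)
    dm_dt[-1] = -g_face[-1] / (0.5 * h)
    dm_dt += np.asarray(mde_production(n, variant, p.alpha)) - p.beta * m

    if variant.has_inhibitor:
        u = fields["u"]
        dm_dt -= p.theta * u * m
        k_face = p.du * np.diff(u) / h
        du_dt = np.empty_like(u)
        du_dt[1:-1] = np.diff(k_face) / h
        du_dt[0] = k_face[0] / (0.5 * h)
        du_dt[-1] = -k_face[-1] / (0.5 * h)
        du_dt += p.xi * f - p.theta * u * m - p.rho * u
        out["u"] = du_dt

    if variant is ModelVariant.BASIC_DIRICHLET:
        dn_dt[-1] = 0.0  # pinned n(1) = 0
        dm_dt[-1] = 0.0  # pinned m(1) = 0

    out["n"] = dn_dt
    out["f"] = df_dt
    out["m"] = dm_dt
    return out


def _jac_sparsity(n_fields: int, M: int) -> sparse.spmatrix:
    tri = sparse.diags([1.0, 1.0, 1.0], [-1, 0, 1], shape=(M, M), format="csr")
    return sparse.kron(np.ones((n_fields, n_fields)), tri, format="csr")


def fd_reference_solve(
    variant: ModelVariant,
    params: InvasionParameters,
    M: int,
    snapshot_times: npt.NDArray[np.float64],
    settings: IntegratorSettings | None = None,
    initial: dict[str, npt.NDArray[np.float64]] | None = None,
) -> UniformGridResult:
    """Solve the same PDE system on M uniform points (independent route).

    ``initial`` maps field names to nodal vectors on the uniform grid; if
    omitted, the closed-form tumour initial condition is used.
    """
    if M < 51:
        raise ValueError(f"reference grid needs M >= 51 points, got {M}")
    if settings is None:
        settings = IntegratorSettings()
    params.validate_for(variant)
    p = params
    x = np.linspace(0.0, 1.0, M)
    names = _field_names(variant)

    if initial is None:
        n0 = np.exp(-(x**2) / p.epsilon)
        initial = {"n": n0, "f": 1.0 - 0.5 * n0, "m": 0.5 * n0}
        if variant.has_inhibitor:
            initial["u"] = np.zeros(M)
    for name in names:
        if name not in initial or np.asarray(initial[name]).shape != (M,):
            raise ValueError(f"initial condition must supply field {name!r} of length {M}")

    times = np.atleast_1d(np.asarray(snapshot_times, dtype=float))
    if np.any(np.diff(times) <= 0) or times[0] < 0:
        raise ValueError("snapshot_times must be ascending and nonnegative")
    if times[0] > 0:
        times = np.concatenate([[0.0], times])

    def odes(t: float, y: npt.NDArray[np.float64]) -> npt.NDArray[np.float64]:
        blocks = dict(zip(names, np.split(y, len(names))))
        d = fd_rhs(variant, params, x, blocks)
        return np.concatenate([d[name] for name in names])

    y0 = np.concatenate([np.asarray(initial[name], dtype=float) for name in names])
    snaps = [ {name: np.asarray(initial[name], dtype=float).copy() for name in names} ]

    later = times[times > 0]
    if later.size:
        sol = solve_ivp(
            odes,
            (0.0, float(later[-1])),
            y0,
            method=settings.method,
            t_eval=later,
            rtol=settings.rel_tol,
            atol=settings.abs_tol,
            max_step=settings.max_step or np.inf,
            jac_sparsity=_jac_sparsity(len(names), M),
        )
        if not sol.success:
            raise IntegrationError(
                f"reference integrator failed: {sol.message}",
                failure_time=float(sol.t[-1]) if sol.t.size else 0.0,
            )
        for j in range(sol.t.size):
            blocks = np.split(sol.y[:, j], len(names))
            snaps.append(dict(zip(names, blocks)))

    fields = {name: np.vstack([s[name] for s in snaps]) for name in names}
    return UniformGridResult(
        variant=variant, params=params, M=M, x=x, times=times, fields=fields
    )


def barycentric_interpolate(
    grid: CollocationGrid,
    values: npt.NDArray[np.float64],
    query: npt.NDArray[np.float64],
) -> npt.NDArray[np.float64]:
    """Evaluate the spectral interpolant at arbitrary points in [0, 1].

    Uses the closed-form barycentric weights of the CGL nodes,
    ``w_i = (-1)^i`` halved at the two endpoints, so evaluation is stable
    for any order used here.
    """
    q = np.atleast_1d(np.asarray(query, dtype=float))
    if np.any(q < 0.0) or np.any(q > 1.0):
        raise ValueError("query positions must lie within [0, 1]")
    v = np.asarray(values, dtype=float)
    x = grid.nodes
    if v.shape != x.shape:
        raise ValueError(f"values must have length {x.size}")
    wts = (-1.0) ** np.arange(x.size)
    wts[0] *= 0.5
    wts[-1] *= 0.5

    diff = q[:, None] - x[None, :]
    exact_q, exact_i = np.nonzero(diff == 0.0)
    np.place(diff, diff == 0.0, 1.0)  # dummy; rows overwritten below
    ratio = wts[None, :] / diff
    out = (ratio @ v) / ratio.sum(axis=1)
    out[exact_q] = v[exact_i]
    return out


def clenshaw_curtis_weights(grid: CollocationGrid) -> npt.NDArray[np.float64]:
    """Quadrature weights on the CGL nodes for integrals over [0, 1].

    Classical Clenshaw–Curtis weights (cosine-sum form) on [-1, 1],
    scaled by 1/2 for the unit interval; exact for polynomials up to
    degree N+1.
    """
    P = grid.N + 1  # number of panels; P+1 nodes
    k = np.arange(P + 1)
    j = np.arange(1, P // 2 + 1)
    b = np.where(j == P / 2, 1.0, 2.0)
    terms = (b / (4.0 * j**2 - 1.0))[None, :] * np.cos(
        2.0 * np.outer(k, j) * np.pi / P
    )
    w = (2.0 / P) * (1.0 - terms.sum(axis=1))
    w[0] /= 2.0
    w[-1] /= 2.0
    return 0.5 * w  # [-1,1] -> [0,1]


def total_mass(grid: CollocationGrid, values: npt.NDArray[np.float64]) -> float:
    """Integral of a nodal field over [0, 1] by Clenshaw–Curtis quadrature."""
    v = np.asarray(values, dtype=float)
    if v.shape != grid.nodes.shape:
        raise ValueError(f"values must be a full-length vector of size {grid.nodes.size}")
    return float(clenshaw_curtis_weights(grid) @ v)


def count_clusters(
    profile: npt.NDArray[np.float64],
    height_frac: float = 0.1,
    dip_frac: float = 0.1,
) -> int:
    """Count cluster peaks of a density profile on a uniform grid.

    A cluster is a local maximum (boundary points compared one-sidedly)
    whose height is at least ``height_frac`` of the global maximum; two
    maxima count as distinct clusters only if the valley between them
    drops below ``(1 - dip_frac)`` times the lower of the two peaks —
    otherwise the shallower structure is absorbed into the taller one.
    """
    p = np.asarray(profile, dtype=float)
    if p.size == 0:
        raise ValueError("profile is empty")
    if not np.all(np.isfinite(p)):
        raise ValueError("profile contains non-finite values")
    if not (0.0 < height_frac < 1.0 and 0.0 < dip_frac < 1.0):
        raise ValueError("height_frac and dip_frac must lie in (0, 1)")
    gmax = p.max()
    if gmax <= 0.0:
        return 0

    # collapse plateaus, keeping one representative index per run
    keep = np.concatenate([[True], np.diff(p) != 0.0])
    idx = np.flatnonzero(keep)
    q = p[idx]
    peaks = [
        idx[i]
        for i in range(q.size)
        if (i == 0 or q[i] > q[i - 1]) and (i == q.size - 1 or q[i] > q[i + 1])
    ]
    peaks = [i for i in peaks if p[i] >= height_frac * gmax]
    if not peaks:
        return 0

    kept = [peaks[0]]
    for i in peaks[1:]:
        valley = p[kept[-1] : i + 1].min()
        if valley < (1.0 - dip_frac) * min(p[kept[-1]], p[i]):
            kept.append(i)
        elif p[i] > p[kept[-1]]:
            kept[-1] = i  # absorb: the taller peak represents the cluster
    return len(kept)


def compare_solutions(
    spectral: SimulationResult,
    reference: UniformGridResult,
    field_name: str,
    time: float,
) -> float:
    """Max-abs discrepancy between the two solvers at one time.

    The spectral snapshot is evaluated on the reference grid through its
    barycentric interpolant before differencing.
    """
    spec = spectral.snapshot(time, field_name)
    ref = reference.snapshot(time, field_name)
    interp = barycentric_interpolate(spectral.grid, spec, reference.x)
    return float(np.max(np.abs(interp - ref)))
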