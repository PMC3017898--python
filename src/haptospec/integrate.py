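"""Stiff time integration of the semidiscrete invasion systems.

The method of lines reduces each model to a small dense ODE system
(3N+3 or 4(N+2) unknowns).  ECM degradation with eta up to ~20 makes the
f-equation moderately stiff, so the default integrator is an adaptive
implicit multistep method (scipy's BDF) with tight tolerances; the dense
systems are small enough that the implicit solves are cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import numpy.typing as npt
from scipy.integrate import solve_ivp

from .chebyshev import BoundaryOperators, CollocationGrid, boundary_operators
from .models import InvasionParameters, ModelVariant, StateVector, rhs

__all__ = ["IntegratorSettings", "SimulationResult", "IntegrationError", "solve"]

#: fields blow past this magnitude -> the run is declared divergent
BLOWUP_LIMIT = 1.0e6

_IMPLICIT_METHODS = ("BDF", "Radau", "LSODA")


class IntegrationError(RuntimeError):
    """Time integration failed; carries the approximate failure time."""

    def __init__(self, message: str, failure_time: float | None = None):
        super().__init__(message)
        self.failure_time = failure_time


@dataclass(frozen=True)
class IntegratorSettings:
    """Tolerances and method for the stiff ODE integrator."""

    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    max_step: float | None = None
    method: str = "BDF"

    def __post_init__(self) -> None:
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_step is not None and self.max_step <= 0:
            raise ValueError("max_step must be positive when given")
        if self.method not in _IMPLICIT_METHODS:
            raise ValueError(
                f"method must be one of {_IMPLICIT_METHODS} (stiffness-capable), "
                f"got {self.method!r}"
            )


@dataclass
class SimulationResult:
    """Snapshots of a run: times x fields x nodes, plus run metadata.

    ``fields[name]`` is an array of shape ``(len(times), N+2)`` on the
    full collocation grid (Dirichlet values included).
    """

    variant: ModelVariant
    params: InvasionParameters
    grid: CollocationGrid
    times: npt.NDArray[np.float64]
    fields: dict[str, npt.NDArray[np.float64]]
    settings: IntegratorSettings
    stats: dict[str, Any] = field(default_factory=dict)

    @property
    def field_names(self) -> list[str]:
        return list(self.fields)

    def snapshot(self, time: float, name: str) -> npt.NDArray[np.float64]:
        """Nodal values of one field at one stored snapshot time."""
        if name not in self.fields:
            raise KeyError(f"no field {name!r}; have {self.field_names}")
        idx = np.flatnonzero(np.isclose(self.times, time, rtol=0.0, atol=1e-12))
        if idx.size == 0:
            raise KeyError(f"time {time} not among snapshots {self.times.tolist()}")
        return self.fields[name][idx[0]]


def _full_snapshot(state: StateVector) -> dict[str, npt.NDArray[np.float64]]:
    return state.full_fields()


def solve(
    variant: ModelVariant,
    params: InvasionParameters,
    grid: CollocationGrid,
    initial: StateVector,
    snapshot_times: npt.NDArray[np.float64],
    settings: IntegratorSettings | None = None,
    ops: BoundaryOperators | None = None,
) -> SimulationResult:
    """Integrate the semidiscrete system and collect snapshots.

    Accepts arbitrary initial states consistent with the variant's layout
    (not only the closed-form tumour initial condition), which makes
    closed-form limit checks possible.  ``snapshot_times`` must be
    ascending and nonnegative; t=0 is prepended if absent and always
    reports the initial state exactly.
    """
    if settings is None:
        settings = IntegratorSettings()
    if ops is None:
        ops = boundary_operators(grid)
    if initial.variant is not variant:
        raise ValueError(
            f"initial state is for variant {initial.variant.value}, expected {variant.value}"
        )
    initial.check_layout(grid)
    params.validate_for(variant)

    times = np.atleast_1d(np.asarray(snapshot_times, dtype=float))
    if times.size == 0 or np.any(np.diff(times) <= 0) or times[0] < 0:
        raise ValueError("snapshot_times must be ascending and nonnegative")
    if times[0] > 0:
        times = np.concatenate([[0.0], times])

    f_end = initial.f_end

    def odes(t: float, y: npt.NDArray[np.float64]) -> npt.NDArray[np.float64]:
        state = StateVector.from_array(y, variant, f_end=f_end)
        return rhs(state, grid, ops, params).to_array()

    def blowup(t: float, y: npt.NDArray[np.float64]) -> float:
        return BLOWUP_LIMIT - float(np.max(np.abs(y)))

    blowup.terminal = True  # type: ignore[attr-defined]

    y0 = initial.to_array()
    snapshots: list[dict[str, npt.NDArray[np.float64]]] = [_full_snapshot(initial)]
    stats: dict[str, Any] = {"nfev": 0, "njev": 0, "nlu": 0}

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
            events=blowup,
            dense_output=False,
        )
        stats = {
            "nfev": int(sol.nfev),
            "njev": int(sol.njev),
            "nlu": int(sol.nlu),
            "status": int(sol.status),
        }
        if sol.status == 1:  # blow-up event fired
            t_fail = float(sol.t_events[0][0]) if sol.t_events[0].size else None
            raise IntegrationError(
                f"solution magnitude exceeded {BLOWUP_LIMIT:g} (divergence)",
                failure_time=t_fail,
            )
        if not sol.success:
            t_fail = float(sol.t[-1]) if sol.t.size else 0.0
            raise IntegrationError(
                f"integrator failed: {sol.message}", failure_time=t_fail
            )
        if not np.all(np.isfinite(sol.y)):
            raise IntegrationError("non-finite values in solution", failure_time=None)
        for j in range(sol.t.size):
            state = StateVector.from_array(sol.y[:, j], variant, f_end=f_end)
            snapshots.append(_full_snapshot(state))

    names = list(snapshots[0])
    fields = {
        name: np.vstack([snap[name] for snap in snapshots]) for name in names
    }
    return SimulationResult(
        variant=variant,
        params=params,
        grid=grid,
        times=times,
        fields=fields,
        settings=settings,
        stats=stats,
    )
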