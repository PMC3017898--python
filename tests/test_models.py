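"""Model assembly: parameters, initial states, semidiscrete right-hand sides."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.interpolate import CubicSpline

from haptospec import (
    CollocationGrid,
    InvasionParameters,
    ModelVariant,
    StateVector,
    boundary_operators,
    fd_rhs,
    get_preset,
    haptotaxis_divergence,
    initial_state,
    mde_production,
    rhs,
    rhs_basic,
    rhs_zero_flux,
)

ZERO_FLUX_VARIANTS = [
    ModelVariant.PROLIFERATION,
    ModelVariant.SATURATING_MDE,
    ModelVariant.INHIBITOR,
]


class TestParameters:
    def test_negative_coefficient_rejected(self):
        with pytest.raises(ValueError, match="gamma"):
            InvasionParameters(gamma=-0.1)

    @pytest.mark.parametrize("field", ["dn", "dm", "epsilon"])
    def test_strictly_positive_fields(self, field):
        with pytest.raises(ValueError):
            InvasionParameters(**{field: 0.0})

    def test_inhibitor_requires_du(self):
        p = InvasionParameters(du=0.0)
        with pytest.raises(ValueError, match="du"):
            p.validate_for(ModelVariant.INHIBITOR)
        p.validate_for(ModelVariant.PROLIFERATION)  # fine without du


class TestInitialState:
    @pytest.mark.parametrize("variant", list(ModelVariant))
    def test_closed_form_at_origin(self, grid30, variant):
        params = InvasionParameters(du=0.001)
        state = initial_state(grid30, params, variant)
        assert state.n[0] == pytest.approx(1.0)
        assert state.f[0] == pytest.approx(0.5)
        assert state.m[0] == pytest.approx(0.5)

    @pytest.mark.parametrize("variant", list(ModelVariant))
    def test_mde_proportional_to_tumour(self, grid30, variant):
        """m(x,0)/n(x,0) = 1/2 at every node, for every variant."""
        state = initial_state(grid30, InvasionParameters(du=0.001), variant)
        assert np.allclose(state.m / state.n, 0.5, rtol=1e-14)
        assert np.allclose(state.f, 1.0 - 0.5 * state.n, rtol=1e-14)

    def test_inhibitor_starts_at_zero(self, grid30):
        state = initial_state(grid30, InvasionParameters(du=0.001), ModelVariant.INHIBITOR)
        assert state.u is not None and np.all(state.u == 0.0)

    def test_dirichlet_layout_and_stored_wall_value(self, grid30):
        params = InvasionParameters()
        state = initial_state(grid30, params, ModelVariant.BASIC_DIRICHLET)
        assert state.n.size == grid30.N + 1
        assert state.f_end == pytest.approx(1.0 - 0.5 * np.exp(-1.0 / params.epsilon))
        full = state.full_fields()
        assert full["n"].size == grid30.N + 2
        assert full["n"][-1] == 0.0 and full["m"][-1] == 0.0

    def test_zero_flux_layout_is_full_length(self, grid30):
        state = initial_state(grid30, InvasionParameters(), ModelVariant.PROLIFERATION)
        assert state.n.size == grid30.N + 2


class TestMdeProduction:
    def test_zero_tumour_means_zero_production(self):
        n = np.zeros(7)
        for variant in ModelVariant:
            assert np.all(mde_production(n, variant, 0.1) == 0.0)

    def test_saturating_law(self):
        n = np.array([0.0, 0.5, 1.0])
        out = mde_production(n, ModelVariant.SATURATING_MDE, 0.1)
        assert out == pytest.approx([0.0, 0.025, 0.0])

    def test_linear_law(self):
        n = np.array([0.0, 0.5, 1.0])
        for variant in (ModelVariant.PROLIFERATION, ModelVariant.INHIBITOR):
            assert mde_production(n, variant, 0.1) == pytest.approx([0.0, 0.05, 0.1])


class TestHaptotaxisDivergence:
    def test_constant_ecm_gives_zero(self, grid30, ops30, rng):
        n = rng.uniform(0, 1, grid30.n_nodes)
        out = haptotaxis_divergence(n, np.full(grid30.n_nodes, 0.7), ops30)
        assert np.max(np.abs(out)) < 1e-9

    def test_no_cells_gives_zero(self, grid30, ops30):
        out = haptotaxis_divergence(
            np.zeros(grid30.n_nodes), grid30.nodes**3, ops30
        )
        assert np.max(np.abs(out)) < 1e-12

    def test_polynomial_exactness(self, grid30, ops30):
        """n = 1, f = x^2: d/dx(n df/dx) = 2 exactly."""
        out = haptotaxis_divergence(
            np.ones(grid30.n_nodes), grid30.nodes**2, ops30
        )
        assert np.allclose(out, 2.0, atol=1e-8)

    def test_length_mismatch_rejected(self, grid30, ops30):
        with pytest.raises(ValueError):
            haptotaxis_divergence(np.ones(5), np.ones(5), ops30)


class TestRhsBasic:
    def test_wrong_variant_rejected(self, grid30, ops30):
        state = initial_state(grid30, InvasionParameters(), ModelVariant.PROLIFERATION)
        with pytest.raises(ValueError):
            rhs_basic(state, grid30, ops30, InvasionParameters())

    def test_empty_tissue_is_fixed_point(self, grid30, ops30, rng):
        """n = m = 0 gives zero time-derivative whatever the ECM profile."""
        size = grid30.N + 1
        f = rng.uniform(0.2, 1.0, size)
        state = StateVector(
            variant=ModelVariant.BASIC_DIRICHLET,
            n=np.zeros(size), f=f, m=np.zeros(size), f_end=0.9,
        )
        d = rhs_basic(state, grid30, ops30, InvasionParameters())
        for block in (d.n, d.f, d.m):
            assert np.max(np.abs(block)) == 0.0

    def test_constant_ecm_reduces_to_pure_diffusion(self, grid30, ops30, rng):
        """With flat ECM the haptotaxis bracket vanishes for any gamma."""
        size = grid30.N + 1
        n = rng.uniform(0, 1, size)
        m = rng.uniform(0, 1, size)
        params = InvasionParameters(gamma=0.05, eta=0.0, alpha=0.0)
        f_end = 0.8
        state = StateVector(
            variant=ModelVariant.BASIC_DIRICHLET,
            n=n, f=np.full(size, f_end), m=m, f_end=f_end,
        )
        d = rhs(state, grid30, ops30, params)
        n_full = np.append(n, 0.0)
        pure = params.dn * (
            ops30.D1 @ (ops30.D0 @ n) + (ops30.row_last @ n_full) * ops30.w
        )
        assert np.allclose(d.n, pure, atol=1e-10)


class TestRhsZeroFlux:
    def test_wrong_variant_rejected(self, grid30, ops30):
        state = initial_state(grid30, InvasionParameters(), ModelVariant.BASIC_DIRICHLET)
        with pytest.raises(ValueError):
            rhs_zero_flux(state, grid30, ops30, InvasionParameters())

    def test_empty_tissue_is_fixed_point(self, grid30, ops30):
        size = grid30.n_nodes
        state = StateVector(
            variant=ModelVariant.INHIBITOR,
            n=np.zeros(size), f=np.full(size, 0.6), m=np.zeros(size),
            u=np.zeros(size),
        )
        params = InvasionParameters(du=0.001, mu2=0.0, xi=0.0, theta=0.05, rho=0.07)
        d = rhs_zero_flux(state, grid30, ops30, params)
        for block in (d.n, d.f, d.m, d.u):
            assert np.max(np.abs(block)) == 0.0

    def test_decoupled_limit_is_neumann_diffusion(self, grid30, ops30, rng):
        """All couplings off: dn/dt collapses to dn * D @ D00 @ n."""
        n = rng.uniform(0, 1, grid30.n_nodes)
        f = rng.uniform(0, 1, grid30.n_nodes)
        params = InvasionParameters(gamma=0.0, eta=0.0, alpha=0.0)
        state = StateVector(
            variant=ModelVariant.PROLIFERATION, n=n, f=f, m=np.zeros_like(n)
        )
        d = rhs_zero_flux(state, grid30, ops30, params)
        assert np.allclose(d.n, params.dn * (grid30.D @ (ops30.D00 @ n)), atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_discrete_wall_flux_cancels_identically(self, seed):
        """The boundary substitution zeroes the tumour flux at both walls."""
        grid = CollocationGrid.from_order(12)
        ops = boundary_operators(grid)
        r = np.random.default_rng(seed)
        n = r.uniform(0, 1, grid.n_nodes)
        f = r.uniform(0, 1, grid.n_nodes)
        params = InvasionParameters(gamma=0.01, dn=0.001)
        s0f = ops.row0 @ f
        sN1f = ops.row_last @ f
        w_bc = np.zeros(grid.n_nodes)
        w_bc[0] = s0f * n[0]
        w_bc[-1] = sN1f * n[-1]
        flux = (
            params.dn * (ops.D00 @ n)
            + params.gamma * w_bc
            - params.gamma * n * (ops.D @ f)
        )
        assert abs(flux[0]) < 1e-12 and abs(flux[-1]) < 1e-12

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_ecm_only_degrades_without_renewal(self, seed):
        """mu2 = 0 and nonnegative m, f imply df/dt <= 0 at every node."""
        grid = CollocationGrid.from_order(10)
        ops = boundary_operators(grid)
        r = np.random.default_rng(seed)
        state = StateVector(
            variant=ModelVariant.PROLIFERATION,
            n=r.uniform(0, 1, grid.n_nodes),
            f=r.uniform(0, 1, grid.n_nodes),
            m=r.uniform(0, 1, grid.n_nodes),
        )
        params = InvasionParameters(eta=10.0, mu1=0.5, mu2=0.0)
        d = rhs_zero_flux(state, grid, ops, params)
        assert np.all(d.f <= 0.0)


@pytest.mark.parametrize("preset_name", ["fig1", "fig8", "fig15"])
def test_rhs_matches_fd_oracle_at_initial_time(preset_name):
    """Spectral RHS of the tumour initial state vs the independent FD route.

    The FD right-hand side is evaluated on 4001 uniform points from the
    closed-form initial condition and interpolated to the collocation
    nodes; each field must agree to 1e-3 max-abs.
    """
    preset = get_preset(preset_name)
    grid = CollocationGrid.from_order(preset.N)
    ops = boundary_operators(grid)
    state = initial_state(grid, preset.params, preset.variant)
    d = rhs(state, grid, ops, preset.params)

    x = np.linspace(0.0, 1.0, 4001)
    n0 = np.exp(-(x**2) / preset.params.epsilon)
    fields = {"n": n0, "f": 1.0 - 0.5 * n0, "m": 0.5 * n0}
    if preset.variant.has_inhibitor:
        fields["u"] = np.zeros(x.size)
    fd = fd_rhs(preset.variant, preset.params, x, fields)

    for name in fields:
        spectral = getattr(d, name)
        nodes = grid.nodes[: spectral.size]
        assert np.max(np.abs(spectral - CubicSpline(x, fd[name])(nodes))) < 1e-3


def test_variant_consistency_on_compatible_smooth_state(grid30, ops30):
    """Dirichlet and zero-flux assemblies agree when both BCs are honoured.

    A state with vanishing value and derivative at x=1 and zero slope at
    x=0 satisfies both boundary treatments; with the production laws
    aligned the two right-hand sides must coincide on interior nodes to
    spectral accuracy.
    """
    x = grid30.nodes
    n = np.cos(np.pi * x / 2) ** 2
    m = 0.5 * np.cos(np.pi * x / 2) ** 2
    f = 0.75 + 0.25 * np.cos(np.pi * x)
    params = InvasionParameters(gamma=0.0, eta=2.0, alpha=0.1, beta=0.3)

    basic = StateVector(
        variant=ModelVariant.BASIC_DIRICHLET,
        n=n[:-1], f=f[:-1], m=m[:-1], f_end=float(f[-1]),
    )
    zf = StateVector(variant=ModelVariant.PROLIFERATION, n=n, f=f, m=m)
    db = rhs_basic(basic, grid30, ops30, params)
    dz = rhs_zero_flux(zf, grid30, ops30, params)
    for name in ("n", "f", "m"):
        interior_b = getattr(db, name)[1:]
        interior_z = getattr(dz, name)[1:-1]
        assert np.max(np.abs(interior_b - interior_z)) < 1e-6
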