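import numpy as np
import pytest

from haptospec import (
    CollocationGrid,
    IntegratorSettings,
    boundary_operators,
    get_preset,
    initial_state,
    solve,
)


@pytest.fixture(scope="session")
def grid30():
    return CollocationGrid.from_order(30)


@pytest.fixture(scope="session")
def ops30(grid30):
    return boundary_operators(grid30)


@pytest.fixture(scope="session")
def fig1_result(grid30):
    """fig1 preset solved once for the whole session (t = 0, 1, 10, 20)."""
    preset = get_preset("fig1")
    state0 = initial_state(grid30, preset.params, preset.variant)
    return solve(
        preset.variant, preset.params, grid30, state0, [0.0, 1.0, 10.0, 20.0]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def loose_settings():
    """Cheap tolerances for tests that only need qualitative solutions."""
    return IntegratorSettings(rel_tol=1e-6, abs_tol=1e-8)
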