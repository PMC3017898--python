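"""Basic invasion run: tumour cells degrade the matrix and break off a cluster.

Solves the three-field model (tumour n, ECM f, MDE m) with a no-flux wall
at x = 0 and tumour/MDE pinned to zero at x = 1, using the published
fig1 parameters (gamma = 0.005, eta = 10, N = 30).
"""

import numpy as np

from haptospec import (
    CollocationGrid,
    barycentric_interpolate,
    count_clusters,
    get_preset,
    initial_state,
    solve,
    total_mass,
)

preset = get_preset("fig1")
grid = CollocationGrid.from_order(preset.N)
state0 = initial_state(grid, preset.params, preset.variant)
result = solve(preset.variant, preset.params, grid, state0, [0.0, 1.0, 10.0, 20.0])

xq = np.linspace(0.0, 1.0, 1001)
print(f"variant={preset.variant.value}  N={preset.N}  ({grid.n_nodes} grid points)")
print("time   mass(n)   max(n)   min(f)   clusters")
for t in result.times:
    n = result.snapshot(t, "n")
    f = result.snapshot(t, "f")
    profile = barycentric_interpolate(grid, n, xq)
    print(
        f"{t:5.1f} {total_mass(grid, n):9.4f} {n.max():8.4f} "
        f"{f.min():8.4f} {count_clusters(profile):6d}"
    )
print()
print("The cluster column counts distinct tumour peaks: the value 2 at")
print("t = 10 and 20 is the secondary cluster breaking off the invading")
print("edge — the numerical signature of metastatic spread. The peak")
print("density drops as cells spread, while the tumour mass stays nearly")
print("constant (the front never reaches the absorbing x = 1 boundary).")
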