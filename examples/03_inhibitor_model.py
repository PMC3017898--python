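"""Four-field model: the matrix fights back with endogenous inhibitors.

The fig15 preset adds an inhibitor field u produced by the ECM at rate
xi*f, neutralising MDEs at rate theta*u*m and decaying at rate rho*u.
"""

import numpy as np

from haptospec import CollocationGrid, get_preset, initial_state, solve, total_mass

preset = get_preset("fig15")
grid = CollocationGrid.from_order(preset.N)
state0 = initial_state(grid, preset.params, preset.variant)
result = solve(preset.variant, preset.params, grid, state0, [0.0, 1.0, 2.0, 10.0, 20.0])

print("time   mass(u)   max(u)   x at max(u)   mass(m)")
for t in result.times:
    u = result.snapshot(t, "u")
    m = result.snapshot(t, "m")
    print(
        f"{t:5.1f} {total_mass(grid, u):9.4f} {u.max():8.4f}"
        f" {grid.nodes[np.argmax(u)]:12.3f} {total_mass(grid, m):9.4f}"
    )
print()
print("Inhibitor concentration starts at zero and rises where the ECM is")
print("still intact (the max sits ahead of the invasion front): the matrix")
print("responds to the enzymes by producing inhibitors.")
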