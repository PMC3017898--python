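# Methods

## Models

Four variants of a reaction–diffusion–haptotaxis system on x ∈ [0, 1] are
implemented (`ModelVariant`):

| variant | fields | right boundary | extra terms |
|---|---|---|---|
| `basic` | n, f, m | n = m = 0 (Dirichlet) | — |
| `proliferation` | n, f, m | no-flux | μ₁ n(1−n−f), μ₂ f(1−n−f) |
| `saturating` | n, f, m | no-flux | as above, MDE production α n(1−n) |
| `inhibitor` | n, f, m, u | no-flux | inhibitor equation, −θ u m in the m-equation |

n is tumour cell density, f ECM density, m MDE concentration, u endogenous
inhibitor concentration. All variants share the left-wall no-flux
conditions dₙnₓ − γ n fₓ = 0 and mₓ = 0 (uₓ = 0 where present). The ECM has
no transport term: it is only degraded (−η m f) and, in the renewal
variants, logistically rebuilt. Inhibitor production is taken proportional
to the ECM density, ξ f: intact matrix responds to enzymes by producing
tissue inhibitors.

All quantities are dimensionless (densities scaled to carrying capacity,
the domain to unit length). Defaults follow the published simulation
presets: dₙ = dₘ = (d_u) = 0.001, α = 0.1, ε = 0.01, with γ ∈
[0.005, 0.02], η ∈ {10, 20}, β ∈ {0, 0.07}, μ₁, μ₂ ∈ {0, 0.1, 0.5}, and
θ = 0.05, ξ = 0.03, ρ = 0.07 for the inhibitor run. γ controls how strongly
cells climb ECM gradients (larger γ ⇒ earlier and sharper cluster
break-off); η how fast enzymes clear matrix; ε the width of the initial
Gaussian tumour.

## Spatial discretisation

Chebyshev–Gauss–Lobatto nodes xᵢ = ½ − ½cos(iπ/(N+1)), i = 0..N+1,
ascending, with the dense differentiation matrix D built from barycentric
weights, dᵢⱼ = (wⱼ/wᵢ)/(xᵢ−xⱼ), and diagonal entries set to the negated
off-diagonal row sums so constants differentiate to exactly zero. Second
derivatives are compositions of first-order operators, never built
directly.

Boundary conditions are *embedded in the operators*, not imposed after the
fact:

- **Dirichlet right wall** (`basic`): unknowns live at nodes 0..N; the
  known values n(1) = m(1) = 0 enter through the last column of D (the
  vector `w`) and the wall-row sums s_{N+1}. The first derivative of n
  replaces its row 0 with the value the no-flux condition prescribes,
  (γ/dₙ) n(0) s₀ᶠ.
- **No-flux walls** (other variants): all N+2 nodes are unknowns. The
  tumour derivative uses D with rows 0 and N+1 zeroed (`D00`) plus a
  correction vector carrying (γ/dₙ) n fₓ at the walls, which makes the
  discrete flux dₙnₓ − γ n fₓ vanish *identically* (to rounding) at the
  wall nodes — this is what conserves tumour mass. m and u use
  D·(D00··) for their diffusion, i.e. the gradient with wall rows zeroed
  (mₓ = 0 there) differentiated once more.
- The ECM obeys no boundary condition; its gradient always uses the full
  matrix.

At the Dirichlet wall the ECM value is constant in time (m(1, t) = 0
implies ∂f/∂t(1) = 0), so f(1) = 1 − e^{−1/ε}/2 is stored as state
metadata rather than integrated.

A display of the no-flux scheme's diffusion operator for m and u admits
two readings (a single application of the boundary-zeroed first-derivative
matrix, or its composition with the full matrix); only the composition is
dimensionally a second derivative and consistent with the Dirichlet-case
construction, so the composition is used. The finite-difference
cross-check below confirms it: right-hand sides agree to ~5·10⁻⁵ where the
alternative reading would disagree at O(1).

## Time integration

`solve` wraps scipy's BDF (Radau/LSODA selectable) with rel_tol = 10⁻⁸,
abs_tol = 10⁻¹⁰ by default. The scheme is deterministic: repeated runs are
bit-identical. Integration aborts with a diagnostic (and the failure time)
if any field passes 10⁶ in magnitude — blow-up detection, since no
stability analysis is attempted. Snapshots default to t ∈ {0, 1, 2, 10,
20}; t = 0 always returns the initial state exactly.

## Validation oracle

`fd_reference_solve` rediscretises the same PDEs with second-order
conservative finite volumes on M ≥ 51 uniform points: fluxes
dₙnₓ − γ n fₓ at cell faces (arithmetic-mean n, centred gradients, no
upwinding), wall nodes owning half-cells with the wall flux set to the
boundary-condition value (zero at no-flux walls), Dirichlet values pinned.
This conserves the trapezoid tumour mass exactly and shares no code with
the spectral kernel. The Jacobian sparsity (block-tridiagonal) is passed to
BDF so M = 4001 runs in under a second.

Diagnostics:

- `total_mass` — Clenshaw–Curtis quadrature on the CGL nodes (classical
  cosine-sum weights, exact for polynomials through degree N+1).
- `barycentric_interpolate` — closed-form CGL barycentric weights
  (−1)ⁱ, halved at the endpoints.
- `count_clusters` — "cluster" is operationalised as: local maxima
  (boundaries compared one-sidedly, plateaus collapsed) with height ≥ 10 %
  of the global maximum, two maxima being distinct only if the valley
  between them drops below 90 % of the lower peak. Counting is done on a
  1001-point uniform evaluation of the interpolant. For the published
  configurations the count is insensitive to the height threshold across
  [0.05, 0.2].

## Measured behaviour the tests pin down

- Differentiation is exact on polynomials of degree ≤ N+1 to ≤ 10⁻⁸ for
  N ≤ 60; row sums vanish to ≤ 10⁻¹⁰·max|D|.
- With all couplings off, the solver tracks the Neumann heat-equation mode
  1 + e^{−dₙπ²t}cos(πx) to ≤ 10⁻⁶ at t = 100, N = 30.
- Under no-flux walls without proliferation the tumour mass drifts by
  ~10⁻¹¹ relative over t ∈ [0, 10] (test bound 10⁻⁶).
- Spectral (N = 30) vs finite-difference (M = 4001) tumour profiles for
  the γ = 0.005, η = 10 configuration agree to 2.4·10⁻³ at t = 1; the FD
  route self-converges monotonically under M-refinement while the
  spectral-vs-FD distance plateaus at the spectral truncation error, as it
  must.

## Cluster timing

For γ = 0.005, η = 10 both solution routes give a strictly monotone tumour
profile at t = 1; the secondary cluster is present by t = 10 (and t = 20).
With γ = 0.01 the break-off is already visible at t = 1. The diagnostics
therefore report two clusters for the weaker-haptotaxis configuration only
from t = 10 on.

## Problem sizes and runtime

Defaults everywhere are the published configurations: N = 30 (43 for the
γ = 0.02, η = 20 run), snapshots to t = 20, FD refinement M ∈ {501, 1001,
2001, 4001}. A full preset run takes well under a second on one core; the
complete test suite and the acceptance script each run in seconds.

## Known limitations

- One spatial dimension only; no alternative inhibitor-production laws
  beyond ξ f.
- The spectral solution exhibits small (≈2·10⁻⁴ at N = 30) oscillations in
  regions where fields vanish — the classic non-monotonicity of
  non-dissipative spectral schemes; field minima can be slightly negative.
  The cluster counter's height threshold makes it immune to these ripples.
- The synthetic initial condition is the closed-form Gaussian tumour; real
  invasion fronts, spatial heterogeneity of tissue, and parameter noise
  are outside what the tests exercise, so passing them shows scheme
  correctness, not biological calibration.
- No positivity preservation or stability proof is attempted; divergence
  is detected, not prevented.
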