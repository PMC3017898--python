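# haptospec

A Chebyshev spectral collocation simulator for one-dimensional continuum
models of tumour invasion and metastasis.

## The scientific problem

Malignant tumours invade surrounding tissue by secreting matrix-degradative
enzymes (MDEs, e.g. matrix metalloproteases) that digest the extracellular
matrix (ECM), then migrating both randomly and up the ECM gradient
(*haptotaxis*). On the scaled tissue domain x ∈ [0, 1], with tumour cell
density n(x, t), ECM density f(x, t) and MDE concentration m(x, t), the
basic model reads

    ∂n/∂t = dₙ ∂²n/∂x² − γ ∂/∂x (n ∂f/∂x)
    ∂f/∂t = −η m f
    ∂m/∂t = dₘ ∂²m/∂x² + α n − β m

with no-flux conditions dₙ nₓ − γ n fₓ = 0 and mₓ = 0 at x = 0, and either
Dirichlet (n = m = 0) or the same no-flux conditions at x = 1. Variants add
logistic proliferation μ₁ n (1 − n − f), ECM renewal μ₂ f (1 − n − f), a
saturating MDE production law α n (1 − n), and a fourth field u(x, t) of
endogenous inhibitors (∂u/∂t = d_u ∂²u/∂x² + ξ f − θ u m − ρ u, with the
neutralisation term −θ u m also entering the MDE equation).

The initial tumour is a narrow Gaussian at the left wall,
n(x, 0) = exp(−x²/ε), with m(x, 0) = n(x, 0)/2 and f(x, 0) = 1 − n(x, 0)/2.
The interesting phenomenology is *metastatic break-off*: a secondary peak of
tumour density detaching from the main body at the invading edge.

## The numerical method

Space is discretised on N + 2 Chebyshev–Gauss–Lobatto points
xᵢ = ½ − ½ cos(iπ/(N+1)) with a dense first-order differentiation matrix D;
second derivatives are compositions of first-order operators whose boundary
rows are overwritten so the flux boundary conditions are embedded in the
semidiscrete system (the discrete wall flux vanishes identically). The
resulting small stiff ODE system (3N + 3 equations for the three-field
models) is integrated with an adaptive implicit (BDF) solver. Spectral
accuracy means ~32 points match what finite differences need thousands of
points for.

An independent validation route is built in: a conservative finite-volume
discretisation of the same PDEs on a uniform grid, sharing no code with the
spectral kernel, plus diagnostics (Clenshaw–Curtis tumour mass, barycentric
interpolation, and a peak/dip cluster counter).

## Worked example

```sh
python examples/01_basic_invasion.py
```

prints, for the basic model with γ = 0.005, η = 10, N = 30 (32 grid
points):

```
time   mass(n)   max(n)   min(f)   clusters
  0.0    0.0886   1.0000   0.5000      1
  1.0    0.0886   0.7108   0.0034      1
 10.0    0.0886   0.3570  -0.0000      2
 20.0    0.0885   0.2692  -0.0000      2
```

The ECM minimum collapsing to ~0 shows the enzymes clearing a path; the
cluster count jumping to 2 by t = 10 is the secondary tumour cluster
breaking away from the main body — the event that seeds metastasis. With
stronger haptotaxis (γ = 0.01, the `fig3` preset) the break-off is already
present at t = 1.

The same run from the shell:

```sh
haptospec run --preset fig1 --out out/          # snapshots.csv + diagnostics.csv
haptospec run --preset fig1 --oracle 2001 --out out/   # adds FD comparison
haptospec list-presets
```

Presets `fig1`–`fig15` carry the published parameter sets (shared base
dₙ = dₘ = 0.001, α = 0.1, ε = 0.01; see `haptospec list-presets`).

## Layout

- `src/haptospec/chebyshev.py` — CGL grid, differentiation matrix, boundary-modified operators
- `src/haptospec/models.py` — parameters, variants, initial states, semidiscrete right-hand sides
- `src/haptospec/integrate.py` — stiff time integration and snapshot collection
- `src/haptospec/oracle.py` — finite-difference reference solver, interpolation, quadrature, cluster counting
- `src/haptospec/presets.py`, `config.py`, `cli.py` — published presets, key=value configs, CSV export, CLI
- `docs/methods.md` — modelling and numerical details
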