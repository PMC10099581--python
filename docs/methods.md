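# Methods

## The model

`stepscale` works with step-selection movement kernels: the probability
density that an animal observed at fixed intervals τ steps from location
**x** to location **z** is

```
p_τ(z | x, α, t) ∝ ψ_τ(|z − x|) · M(α) · exp(β · Z(x, z, t))
```

where ψ_τ is a selection-free step-length component (exponential-decay,
Gaussian, uniform or delta), M(α) an optional von Mises turn-angle factor
with concentration κ, **Z** a vector of movement covariates (habitat
layers, distances to a central place, other animals' occurrence
distributions) and **β** the selection coefficients a step-selection
analysis estimates.  The kernel is truncated to the study area Ω — no
probability mass ever leaves the grid ("no go" boundary) — and normalised
over the admissible cells by the midpoint rule, so the per-cell
distribution is exactly stochastic.

The package does **not** fit β from telemetry; it consumes fitted (or
hypothesised) coefficients and scales them up to space-use patterns.

### Conventions

* Grid cells are half-open unit squares (configurable cell size), origin
  at the lower-left corner; continuous coordinates map to their
  containing cell.  Internally row 0 is the bottom row; the ESRI ASCII
  writer flips to the top-row-first disk layout.
* Bearings are radians clockwise from north (+y); a step due east has
  bearing π/2.
* Distances are Euclidean between cell centres, in coordinate units.
* Step lengths enter ψ directly as |z − x| (not |z − x|/τ); with the
  default τ = 1 the two parameterisations coincide.
* β is treated as constant in τ.

### The central-place covariate is an end-point covariate

The resource-plus-central-place kernel used throughout the examples has
unnormalised weight

```
exp(−λ|z − x|) · exp(β_R R(z) − β_C |z − x_C|)
```

with the distance to the den/nest site x_C evaluated at the step
**end-point z**.  A start-point distance |x − x_C| would be constant in z
and cancel identically in the normalisation — the kernel would show no
localising tendency at all.  Evaluating it at z both produces the
intended attraction and keeps the kernel in the end-point-only class for
which the closed-form steady state below is exact.  The `Covariate` type
still supports start-point evaluation (`at="start"`) for covariates that
genuinely act on departure.

## Master-equation propagation

Discretising the propagation integral over cells turns one fix interval
into a column-stochastic matrix product `U(t+τ) = P U(t)`, with
`P[s, s'] = p_τ(s | s')` assembled column-by-column from the kernel
evaluated at each source-cell centre.  Propagation renormalises each step
(round-off drift is ~1e-15 per step; conservation holds to 1e-9 over
thousands of steps).  Matrices are dense by default; a sparse CSC path
(entries below 1e-12 dropped, columns renormalised) is available for
grids beyond ~10⁴ cells.

The engine requires κ = 0: a turn-angle component would need a
bearing-augmented state space, which is out of scope — the
individual-based model supports κ > 0 instead.

The *cumulative* UD, `(1/T) Σ_t u(·, t)`, is the quantity that
trajectory-resampling estimators report.  It equals the steady state only
after convergence; `cumulative_ud` exists so users can measure the
discrepancy for transient systems.

### Steady states

`steady_state_fixed_point` runs power iteration (defaults: L1 tolerance
1e-10, max 10⁶ iterations) and returns iteration count, final residual
and a convergence flag.  Non-convergence is a first-class result, not an
error, because kernels coupled to their own history can oscillate
indefinitely.  `steady_state_eigen` solves the same fixed point from the
leading eigenvector; degenerate unit-eigenvalue multiplicity
(disconnected chains) is flagged.  The two agree to <1e-8 L1 on
irreducible systems and cross-check each other in the test suite.

## Closed-form steady states

For ψ radially symmetric and covariates depending only on the step
end-point (`Z̃(z)`), the exact steady state is

```
u*(x) ∝ exp(β·Z̃(x)) · ∫_Ω exp(β·Z̃(z)) ψ(|x − z|) dz .
```

The discrete analogue satisfies detailed balance with the discretised
kernel exactly — `P(s|s') u*(s') = P(s'|s) u*(s)` — so the closed form and
the numerical steady state agree to solver precision (~1e-10 L1 in
practice; the acceptance test asserts 1e-3).  The inner integral uses the
same midpoint rule as the kernel normalisation, with ψ truncated where it
falls below 1e-12 of ψ(0), and is evaluated in memory-bounded blocks of
the pairwise distance matrix.

Two limits:

* ψ uniform over Ω (the animal can cross the whole study area in one
  step): the inner integral is constant and u* collapses to the classical
  resource-selection function `exp(β·Z̃)/Σ exp(β·Z̃)` — slope 1 when
  regressing log u* on β·Z̃.
* ψ narrower than one cell (selection at a much finer scale than the
  landscape): only the local term survives and u* ∝ exp(2β·Z̃) — slope 2.
  The effect of selection on space use **doubles** between the two
  movement-scale extremes; intermediate ψ interpolate.

The wide-kernel limit over-estimates and the narrow-kernel limit
under-estimates the occupied area: for a localising kernel the 95%
highest-density regions nest as RSF ⊇ exact ⊇ doubled.  Highest-density
regions are computed by sorting cells by density and accumulating to the
target mass — no smoothing, fully reproducible.

With β = 0 the RSF and doubled formulas are exactly uniform, but the
exact formula is not: the no-go boundary depresses `∫ψ(|x−z|)dz` near
the edge, so even a selection-free animal is slightly less likely to be
found at the boundary.  This is a real property of the truncated kernel,
not a numerical artefact.

## Diffusion constant

The advection–diffusion (PDE) limit of the master equation has diffusion
constant `D_τ = (1/4τ) ∫_{R²} |x′|² ψ(|x′|) dx′`.  A dimensionally
meaningful D requires ψ to be a probability density, so the
implementation normalises ψ over the plane before taking the moment
(adaptive radial quadrature, relative tolerance 1e-11).  For the
normalised 2-D exponential with rate λ this gives `D = 3/(2λ²)`
(`∫r³e^{−λr}dr = 6/λ⁴` against normaliser `2π∫re^{−λr}dr·(2π)⁻¹ = 1/λ²`),
and `σ²/2` for an isotropic Gaussian; both closed forms are frozen in the
tests against the quadrature.  A delta kernel gives 0; a uniform kernel
has no normalisable density over the plane and is rejected.  The full
PDE is not solved numerically — its steady state is the doubled-β closed
form, which is implemented; the master equation covers transient
dynamics.

## Individual-based simulation

`sample_step` draws the next cell by exact categorical sampling of the
kernel probabilities (inverse-CDF; no MCMC, no rejection), then jitters
uniformly within the cell so trajectories live in continuous space.
`simulate_replicates` applies the identical per-cell law vectorised
across replicates via cached column CDFs of the transition matrix, making
10⁴ replicates over 50 steps a sub-second operation; replicate end-points
are genuinely independent samples of u(x, t) and are smoothed into a UD
estimate by `endpoint_ud`.

### Occurrence distributions and coupling

An animal's occurrence distribution (OD) summarises its *recent* space
use: the last `od_window` steps (default 500) are interpolated with
`stepping_stones_per_step` straight-line stepping stones (default 10,
end-points counted once) — a simple stand-in for the locations visited
between fixes — and smoothed with a fixed-bandwidth Gaussian KDE
(default bandwidth 2 cell units, scikit-learn `KernelDensity`), evaluated
at cell centres and normalised to sum 1.  Continuous-time OD estimators
exist; fixed-bandwidth KDE was chosen for reproducibility and speed, and
because kernels plausibly respond to a smoothed version of recent use.

Coupled systems wire each animal's OD into the other animals' kernels as
a dynamic end-point covariate.  During simulation:

* animals move in a freshly randomised order each step (no animal is
  systematically first; the update scheme is effectively asynchronous);
* ODs refresh every `od_update_interval` steps (default 1) using steps
  strictly before the current time, keeping the feedback causal;
* before an animal has moved, its OD is uniform, so interactions exert
  no force at t = 0.

Because ODs are normalised densities, per-cell values on an n-cell grid
are O(1/n-of-the-home-range) — around 0.01 on the grids used here — so
interaction coefficients β_{j,j′} are naturally O(10–100) when the
interaction should shift log-weights by O(1).  Coefficients are in units
of inverse OD density; this is a unit convention, not a strength claim.

## Synthetic landscapes

`generate_resource_layer` low-pass filters white noise with a Gaussian of
standard deviation `smoothness` cells (reflect boundary) and min-max
rescales to [0, 1] — a smooth, seeded, reproducible resource surface.
It emulates the spatial autocorrelation of real resource layers but none
of their anisotropy, patch topology or temporal dynamics; passing tests
show the machinery is internally consistent on smooth fields, not that
any particular ecological system is well described.  Note the rescale
normalises amplitude away: increasing `smoothness` increases spatial
autocorrelation and decreases local roughness, but does not shrink the
[0, 1] range.

## Problem sizes and defaults used in the checks

The test suite exercises the full 100×100 grid for kernel normalisation,
20×20 grids for steady-state identities (400-cell transition matrices
solve in milliseconds), a 50×50 grid for the region-ordering comparison,
10⁴ replicate paths over 50 steps on a 10×10 grid for the
stochastic-vs-deterministic consistency check (a strongly localising
kernel, λ = 1, β_R = 1.5, β_C = 2, keeps the sampling-noise floor of the
total-variation statistic well below the asserted 0.02), and paired
two-animal runs on a 30×30 grid (200 steps, avoidance 100 in OD-density
units vs 0, ten seed pairs, one-sided sign test) for the
missing-covariate directionality check.  These sizes were chosen so each
check isolates one property at high signal-to-noise; all scale up by
changing one argument.

## Known limitations

* No bearing-indexed master equation: κ > 0 is simulation-only.
* No numerical PDE solver, linear stability or weakly nonlinear
  analysis; the `sweep` command provides an empirical
  segregation-vs-interaction-strength curve only.
* No coefficient estimation from data, no CRS/projection handling, no
  continuous-time formulation.
* Steady-state solvers refuse time-varying and coupled kernels — for
  those, only simulation (and its emergent ODs/UDs) is meaningful.
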