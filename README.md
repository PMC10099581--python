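# stepscale

Scale step-selection movement kernels up to space-use patterns.

Step selection analysis (SSA/iSSA) is the standard way to infer the
drivers of animal movement from telemetry: it compares each observed step
against the alternatives the animal could have taken, yielding selection
coefficients **β** and, less well appreciated, a fully parametrised
*movement kernel*

```
p_τ(z | x, t) ∝ ψ_τ(|z − x|) · exp(β · Z(x, z, t)) ,
```

the probability of stepping from **x** to **z** in one fix interval τ.
`stepscale` is for ecologists and modellers who want to propagate that
kernel forward to the broad-scale patterns it implies — utilisation
distributions (UDs), home ranges, territory mosaics — and to use the
mismatch between predicted and observed patterns as a goodness-of-fit
probe for missing covariates.  It provides:

* **Master-equation propagation** — the kernel discretised to a
  column-stochastic transition matrix over raster cells,
  `U(t+τ) = P U(t)`, with the "no go" boundary (no mass leaves the study
  area), cumulative-UD accumulation, and steady-state solvers (power
  iteration and eigen-solve) with explicit convergence diagnostics.
* **Closed-form steady states** — for kernels with radially symmetric ψ
  and end-point-only covariates,
  `u*(x) ∝ exp(β·Z̃(x)) ∫ exp(β·Z̃(z)) ψ(|x−z|) dz` (exact), together
  with its uniform-ψ limit `u* ∝ exp(β·Z̃)` (the classical resource
  selection function) and its narrow-ψ limit `u* ∝ exp(2β·Z̃)` — the
  selection coefficients *double* when movement decisions happen at a
  much finer scale than the landscape.
* **Individual-based simulation** — exact categorical sampling of the
  kernel, single or coupled animals, with between-animal interactions
  mediated by occurrence distributions (recent paths, stepping-stone
  interpolated and KDE-smoothed) fed back into the kernels as dynamic
  covariates.
* **Pattern metrics** — Bhattacharyya affinity for UD/OD overlap,
  locational variance for UD size, a segregation index for interaction
  sweeps.
* **A CLI** (`stepscale generate-landscape | propagate | steady |
  steady-analytic | simulate | od | compare | sweep`) over ESRI ASCII
  rasters and CSV trajectories, with seeds and run manifests recorded
  next to every output.

The diffusion constant of the advection–diffusion (PDE) limit,
`D_τ = (1/4τ)∫|x′|²ψ(|x′|)dx′` with ψ normalised to a planar density, is
also provided (`diffusion_constant`); see `docs/methods.md` for the model
details, conventions and limitations.

## Worked example

A smooth synthetic resource layer, an animal with exponential step
lengths (λ = 0.2), resource selection (β_R = 1.5) and central-place
attraction (β_C = 0.2) towards a den at the grid centre:

```python
import numpy as np
from stepscale import *

resource = generate_resource_layer(50, 50, smoothness=5, seed=42)
spec = make_resource_central_place_kernel(resource, (25.0, 25.0),
                                          lam=0.2, beta_r=1.5, beta_c=0.2)

P = build_transition_matrix(spec)
numeric = steady_state_fixed_point(P, tol=1e-10)

exact = steady_state_barnett_moorcroft(spec.selection_free, spec.beta,
                                       spec.covariates, spec.study_area)
rsf = steady_state_rsf(spec.beta, spec.covariates, spec.study_area)
doubled = steady_state_doubled(spec.beta, spec.covariates, spec.study_area)

rep = compare_steady_states(exact, rsf, doubled, numeric.ud)
```

prints, via the obvious `print` calls:

```
power iteration: converged=True after 33 iterations (L1 residual 7.69e-11)
L1(exact, numeric)  = 8.16e-11
95% HDR area: rsf=1469 >= exact=764 >= doubled=490 cells
BA(exact, rsf)     = 0.9626
BA(exact, doubled) = 0.9775
diffusion constant D = 37.5 (3/(2*0.2^2) = 37.5)
```

Reading the numbers: the closed form and the numerically iterated steady
state agree to solver precision (it is an exact stationary distribution
of the discretised kernel, by detailed balance).  The 95%
highest-density-region areas order as RSF ≥ exact ≥ doubled: ignoring
movement constraints (the RSF limit) over-estimates the home range by
roughly a factor two here, while assuming arbitrarily fine-scale
selection (the doubled limit) under-estimates it.  The Bhattacharyya
affinities quantify how close each approximation is to the exact UD.

Coupled animals with mutual avoidance:

```python
cfg = coupled_simulation_config(
    resource,
    centres=[(15.0, 25.0), (35.0, 25.0)],
    lam=0.5, beta_r=1.0, beta_c=0.2,
    interaction=100.0 * (np.ones((2, 2)) - np.eye(2)),  # mutual avoidance
    n_steps=500, seed=1,
)
result = simulate(cfg)
ba = bhattacharyya_affinity(result.final_ods[0], result.final_ods[1])
```

Re-running with `interaction=np.zeros((2, 2))` and the same seed raises
the overlap `ba` — exactly the signature one uses, in reverse, to detect
an avoidance covariate missing from a fitted movement model.

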