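# Methods

## Model

The reconstruction problem is `min_{x≥0} D(Ax + r, y) + β S(x)` with the
Poisson/KL fidelity `D(s, t) = Σ_j d(s_j, t_j)`,
`d(s,t) = s − t + t log(t/s)` (with `d(s,0) = s` and `+∞` off the feasible
branches), and the relative difference prior

    S(x) = ½ Σ_i Σ_{j∈N_i} w_ij κ_i κ_j φ(x_i + x_j, x_i − x_j),
    φ(s, d) = d² / (s + γ|d| + ε).

`D` is separable over sinogram bins, hence over view subsets: the smooth
objective splits as `J = Σ_i J_i` with `J_i = D_i + (β/n) S`, which is what
the stochastic estimators sample.

### RDP derivatives

With `den = s + γ|d| + ε` the pair term has the closed forms

    ∂φ/∂x_i = (2 d·den − d² − γ d|d|) / den²
    ∂φ/∂x_j = (−2 d·den − d² + γ d|d|) / den²
    ∂²φ/∂x_i² = 2 (2 x_j + ε)² / den³,   ∂²φ/∂x_j² = 2 (2 x_i + ε)² / den³

(the second derivatives follow from `den − (1 + γ·sign d)·d = 2 x_j + ε`).
All terms are smooth for ε > 0 because `d²·sign(d) = d|d|`. Every analytic
derivative is validated against central finite differences in the test
suite; the diagonal Hessian grows like `2/(2x+ε)` in cold regions, which is
exactly why the prior-aware preconditioner matters there.

A consequence worth noting: for nonnegative voxels the pair sum always
dominates the difference (`s ≥ |d|`), so the low-activity slope of the
prior per unit difference is `1/(1+γ)`, approaching the total-variation
slope `1/γ` only for large γ.

## Parameters and defaults

| parameter | default | meaning / rationale |
|---|---|---|
| γ | 2 | edge preservation; standard clinical choice, configurable |
| ε | 1e-3 × mean nonzero activity of the init image | keeps φ smooth at a scale-free magnitude across count levels; recorded per run |
| κ | 1 everywhere | per-voxel weights are pluggable (config hook) but default to ones |
| neighborhood | 8 neighbors in 2D (26 in 3D), w = 1/distance (mm) | the established RDP convention; edge-crossing pairs dropped |
| δ (preconditioner) | 1e-6 × max of the init image | only needs to be positive; recorded per run |
| α (harmonic weight) | 1 | plain inverse-sum combination; exposed for sensitivity studies |
| ω (SVRG period) | 2 | snapshot + full gradient refreshed every 2n updates |
| subsets n | divisor of n_views closest to 25 (24.2 for alg3) | ties broken toward the smaller divisor |
| stepsize | vanishing τ0/(1+ηk/n), τ0 = 1, η = 0.02 | the configuration that converges reliably with the harmonic preconditioner |
| β | β̃ · 2e-4 · true_counts / 3e7 | count-level scaling that keeps resolution comparable across count levels at fixed β̃ |

Epoch accounting: update k counts subset steps from 0; epoch e (1-based)
covers updates (e−1)·n … e·n − 1. Preconditioner update epochs are given
1-based (alg1: 1,2,3; alg2/3: 1,2,4,6) and applied at the epoch start; the
epoch-1 diagonal is computed at the OSEM initialization image.

### Estimator conventions

The objective is a *sum* over subsets, so the unbiased forms are

    SGD:  n ∇J_i(x)
    SAGA: n (∇J_i(x) − g_i) + Σ_j g_j,   table g_i ← ∇J_i(x) afterwards
    SVRG: n (∇J_i(x) − ∇J_i(x̂)) + ĝ,     ĝ = Σ_i ∇J_i(x̂)

each of which averages to ∇J exactly over the n subset choices (asserted
by exact enumeration in the tests). SVRG stores only the snapshot image
and its full gradient, recomputing ∇J_i(x̂) per update; the snapshot is the
current iterate at refresh time. SAGA's table is initialized with the
subset gradients at the start image (one full pass), so the estimator is
unbiased from the first update.

Short-form Barzilai–Borwein steps `τ_bb = p·q / q·q` use consecutive SVRG
snapshots and their full gradients (plain Euclidean products). With ω = 2
the refreshes at k = 2n, 4n, 6n coincide with the ends of epochs 2, 4 and
6, which is where the alg2/alg3 presets recompute τ_bb; a nonpositive
curvature p·q keeps the previous step. The alg2/3 schedule caps the step
at 3 (k < 10), 2.2 (10 ≤ k < 2n), 1 (k ≥ 2n); alg1 uses the fixed ladder
3 / 2 / 1.5 / 1 / 0.5 with breakpoints at k = 10, 100, 200, 300.

Cofactor order: generators of Z_n (k coprime with n) are ranked ascending
by `min(|k − 0.3n|, |k − 0.7n|)` with ties toward the smaller k; epoch e
traverses (0, g, 2g, …) mod n with the e-th ranked generator, cycling when
the list is exhausted. The combination rule (minimum of the two distances)
and the tie-break are our pinned reading of the ranking and are logged
with every run. Whether `without_replacement` reuses one fixed permutation
(alg1's "fixed random sequence") or redraws per epoch is a config flag;
alg1 defaults to the fixed mode.

## Desk-scale simulation

The generator emulates a 2D ring-scanner acquisition at desk scale:

- **geometry** — 96×96 voxels at 2.5 mm; 90 views over 180°, 128 radial
  bins at 2.5 mm. A named full-scale 3D configuration is not part of CI.
- **projector** — explicit sparse pixel-driven matrix (linear splat of each
  voxel center onto the two nearest radial bins, weighted by voxel area /
  bin width). Any matched forward/adjoint pair is equivalent for algorithm
  validation; an explicit sparse matrix makes the adjoint the exact
  transpose and keeps desk-scale cost trivial. Verified against an
  independent scalar-loop oracle.
- **resolution** — 4 mm FWHM isotropic Gaussian in image space, truncated
  at 4σ, zero boundary; the symmetric kernel keeps the blur self-adjoint.
- **attenuation** — water μ = 0.0096 mm⁻¹ inside the body ellipse at
  511 keV; per-bin survival factors exp(−P μ).
- **calibration** — a scalar detection efficiency (2e-6 counts per unit
  activity line-integral) fixes the absolute scale linking activity to
  counts. Because the β scaling rule is expressed in absolute counts, this
  calibration determines the prior-to-likelihood balance; the desk value
  was fixed once, by inspecting converged references only, so that the
  β̃ ∈ {1, 4, 16} ladder spans mild to strong smoothing (body std ratio vs
  truth 0.96 / 0.90 / 0.81) as in the full-scale study design.
- **phantom** — one warm body ellipse (background, activity 1) with a hot
  (4×), a cold (0.1×) and a small hot (2×) insert; any elliptical layout
  is admissible, this one is fixed for determinism.
- **data** — the phantom is rescaled so expected trues sum exactly to the
  target (default 5×10⁵); the background `r` is the true sinogram smoothed
  with σ = 10 bins, scaled to 25 % of prompts and floored at a small
  positive value; `y` is one Poisson draw from a generator keyed by the
  dataset seed.

What the generator does **not** model: time-of-flight, scatter/randoms
physics (the smooth background is a surrogate), detector normalization,
dead time, out-of-FOV activity, and the inverse-crime gap (data are
simulated with the same operator used for reconstruction). Passing tests
therefore demonstrate optimizer correctness and the preconditioner effect,
not clinical image quality.

## Metrics and reference

Whole-object NRMSE = RMS deviation over the body-ellipse interior
(excluding the cold exterior), normalized by the activity of the largest
background ellipse; the practical-convergence marker is NRMSE < 0.01
sustained over all later recorded points. VOI error is the absolute
difference of VOI means with the same normalization (the exact challenge
formula is not public; this form is isolated in one function so it can be
swapped). The reference `x_ref` is L-BFGS-B on the bound-constrained
problem with variables rescaled by the square root of the harmonic
diagonal at the start image — scaffolding for evaluation, not part of the
contribution.

## Numerical choices and edge cases

- Bins with `y = 0` contribute gradient `A_iᵀ1`; `0/0` ratios are treated
  as 0. The background floor keeps `Ax + r > 0` wherever counts occur.
- Voxels with zero (subset) sensitivity are frozen: preconditioner diagonal
  0, OSEM multiplier 1.
- All RDP routines require post-prox (nonnegative) iterates; feasibility
  is enforced by the update, not re-checked per pair.
- Importance-sampling probabilities are floored at 0.1/n and renormalized
  to avoid starving subsets; they refresh at SVRG snapshot points from the
  subset-gradient norms that the snapshot pass computes anyway.
- Problem sizes in tests: most properties run on a 16×16 / 12-view
  instance; the end-to-end convergence checks use the full desk dataset
  (100 epochs ≈ 20 s single-core).

## Known limitations

- 3D support is a thin extension (plane-replicated transaxial projector);
  the desk defaults are 2D.
- The cofactor ranking rule and the BB timing ("end of epochs 2, 4, 6")
  are pinned readings of ambiguous descriptions; both are exposed as
  configuration so alternatives can be compared.
- `reference_solve` declares convergence by iteration budget plus
  projected-gradient report; pathological configurations (β = 0 with heavy
  blur) converge slowly and need larger budgets.
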