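# rdpet

Stochastic variance-reduced reconstruction for PET with the relative
difference prior (RDP) and prior-aware preconditioning.

## The problem

Clinical PET reconstruction is posed as the convex optimization problem

```
x* ∈ argmin_{x ≥ 0}  D(Ax + r, y) + β S(x)
```

where `y` is the measured sinogram of coincidence counts, `A` a linear
forward model (geometry, resolution, attenuation), `r` an additive
background (scatter + randoms), `D` the Kullback–Leibler / Poisson data
fidelity, and `S` the relative difference prior

```
S(x) = ½ Σ_i Σ_{j∈N_i} w_ij κ_i κ_j (x_i − x_j)² / (x_i + x_j + γ|x_i − x_j| + ε)
```

which penalizes *relative* rather than absolute neighbor differences:
differences between hot voxels are cheap, the same difference in cold
regions costs ≈ |x_i − x_j|/(1+γ).

Fast solvers exploit the separability of `D` over view subsets with
stochastic gradient estimators and the preconditioned proximal step

```
x(k+1) = prox_{≥0}( x(k) − τ(k) D(k) ∇̃(k) )
```

This package implements the whole design space of that iteration:

- **estimators** — SGD, SAGA (gradient table), SVRG (snapshot + full
  gradient, refreshed every ω·n updates);
- **preconditioners** — the classic MLEM diagonal `(x+δ)/AT1`, and the
  harmonic-mean combination with the inverse diagonal Hessian of `βS`,
  `D(x) = (x+δ) / (AT1 + α · diagH_{βS}(x) · (x+δ))`, which is what makes
  unit stepsizes stable under strong regularization;
- **subset orders** — Herman–Meyer, with/without replacement, importance
  sampling by subset-gradient norms, and the cofactor order (cyclic-group
  traversal with generators ranked by proximity to 0.3n and 0.7n);
- **stepsizes** — constant, vanishing `τ0/(1+ηk/n)`, short-form
  Barzilai–Borwein, and the two piecewise preset schedules;
- **presets** — `alg1`, `alg2`, `alg3`: the three closely related
  SVRG + harmonic-preconditioner configurations, differing only in subset
  target (25 vs 24.2), subset order, preconditioner update epochs
  (1,2,3 vs 1,2,4,6) and stepsize rule;
- a **desk-scale simulated scanner** (sparse matched projector, image-space
  Gaussian resolution, water attenuation, smooth background, Poisson noise)
  so every claim can be exercised in seconds without external data, plus a
  converged L-BFGS-B reference solver and NRMSE/VOI metrics.

## Worked example

```python
import numpy as np
from rdpet import (default_desk_setup, simulate_dataset, beta_from_relative,
                   preset_config, run_reconstruction, convergence_update)
from rdpet.optim import osem_init, reference_solve
from rdpet.objective import ObjectiveBundle, RDPParams, epsilon_from_image
from rdpet.sampling import partition_views, choose_num_subsets

grid, geom, spec, model = default_desk_setup()          # 96×96 @ 2.5 mm, 90 views
ds = simulate_dataset(model, spec, true_counts=5e5,
                      background_fraction=0.25, seed=0)

n = choose_num_subsets(geom.n_views, 25.0)              # divisor of 90 nearest 25
scheme = partition_views(geom.n_views, n)
x0 = osem_init(ObjectiveBundle(model, ds.y, ds.r, scheme,
               RDPParams(beta=0.0, gamma=2.0, epsilon=1.0,
                         spacing=grid.spacing)), n_init=27)
beta = beta_from_relative(4.0, ds.true_counts)
bundle = ObjectiveBundle(model, ds.y, ds.r, scheme,
                         RDPParams(beta=beta, gamma=2.0,
                                   epsilon=epsilon_from_image(x0),
                                   spacing=grid.spacing))
x_ref, info = reference_solve(bundle, x0=x0)            # converged reference

cfg = preset_config("alg2", beta_rel=4.0, epochs=10)
x, hist = run_reconstruction(cfg, ds, x_ref=x_ref)
idx = convergence_update(np.asarray(hist["nrmse"][1:]), 0.01)
print(f"converged at epoch {idx + 1}")
```

prints

```
simulated 667516 prompts (500000 expected trues)
n = 30 subsets, beta = 1.33e-05, reference objective = 6706.39
epoch  0  NRMSE = 0.23889
epoch  1  NRMSE = 0.05185
epoch  2  NRMSE = 0.05486
epoch  3  NRMSE = 0.00842
epoch  4  NRMSE = 0.00620
epoch  5  NRMSE = 0.00170
...
converged (NRMSE < 0.01, sustained) at epoch 3
```

NRMSE is the root-mean-square deviation from the converged reference over
the phantom body, normalized by the background activity; 0.01 is the
standard marker of practical convergence. The SVRG run with the
harmonic-mean preconditioner sustains it from epoch 3 (90 subset updates).

The same workflow is available from the shell:

```bash
rdpet simulate --seed 0 --counts 5e5 --out data/desk
rdpet reconstruct --dataset data/desk --seed 0 --out runs/alg2
rdpet evaluate --run runs/alg2
rdpet sweep --config sweep.yaml --dataset data/desk --out sweep.csv
```

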