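"""Stochastic solvers for RDP-regularized PET reconstruction.

The main iteration is the preconditioned proximal stochastic gradient step

    x(k+1) = prox_{>=0}( x(k) - tau(k) D(k) grad_tilde(k) ),

where grad_tilde is one of three estimators of grad J = grad(D + beta S):

* SGD:   n grad J_i(x)
* SAGA:  n (grad J_i(x) - g_i) + sum_j g_j, with table update g_i <- grad J_i(x)
* SVRG:  n (grad J_i(x) - grad J_i(x_hat)) + g_hat, where the snapshot x_hat
         and its full gradient g_hat are refreshed every omega*n updates
         (only the snapshot image and full gradient are stored; the subset
         gradient at the snapshot is recomputed per update).

All three average to the exact full gradient over the n subset choices.
``run_reconstruction`` wires estimators to the preconditioners, subset
samplers and stepsize rules, with three named presets (alg1/alg2/alg3)
binding the hyperparameter sets of the submitted challenge algorithms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import scipy.optimize

from .metrics import nrmse
from .objective import ObjectiveBundle, epsilon_from_image, prox_nonneg, RDPParams
from .phantom import SimulatedDataset, beta_from_relative
from .precond import PreconditionerState
from .sampling import (
    StepsizeRule,
    SubsetSampler,
    bb_short,
    choose_num_subsets,
    partition_views,
)

__all__ = [
    "EstimatorState",
    "ReconConfig",
    "estimator_gradient",
    "apply_update",
    "osem_init",
    "reference_solve",
    "run_reconstruction",
    "preset_config",
]


# --------------------------------------------------------------------------
# gradient estimators
# --------------------------------------------------------------------------

@dataclass
class EstimatorState:
    """Memory of a stochastic gradient estimator.

    SAGA keeps a per-subset gradient table ``grad_table`` and its running sum;
    SVRG keeps a snapshot image and the full gradient at the snapshot, and
    refreshes both every ``omega * n`` updates.
    """

    kind: str
    n: int
    grad_table: list[np.ndarray] | None = None
    grad_table_sum: np.ndarray | None = None
    snapshot: np.ndarray | None = None
    full_gradient: np.ndarray | None = None
    omega: int = 2
    updates_since_snapshot: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("sgd", "saga", "svrg"):
            raise ValueError(f"unknown estimator kind {self.kind!r}")

    @classmethod
    def sgd(cls, n: int) -> "EstimatorState":
        return cls("sgd", n)

    @classmethod
    def saga(cls, bundle: ObjectiveBundle, x0: np.ndarray) -> "EstimatorState":
        """Table filled with the subset gradients at x0 (one full pass)."""
        table = [bundle.subset_gradient(x0, i) for i in range(bundle.n_subsets)]
        return cls(
            "saga",
            bundle.n_subsets,
            grad_table=table,
            grad_table_sum=np.sum(table, axis=0),
        )

    @classmethod
    def svrg(cls, bundle: ObjectiveBundle, x0: np.ndarray, omega: int = 2) -> "EstimatorState":
        g = np.sum([bundle.subset_gradient(x0, i) for i in range(bundle.n_subsets)], axis=0)
        return cls(
            "svrg",
            bundle.n_subsets,
            snapshot=x0.copy(),
            full_gradient=g,
            omega=omega,
        )

    def refresh_snapshot(self, bundle: ObjectiveBundle, x: np.ndarray) -> None:
        assert self.kind == "svrg"
        self.snapshot = x.copy()
        self.full_gradient = np.sum(
            [bundle.subset_gradient(x, i) for i in range(self.n)], axis=0
        )
        self.updates_since_snapshot = 0


def estimator_gradient(
    state: EstimatorState, bundle: ObjectiveBundle, x: np.ndarray, i: int
) -> np.ndarray:
    """Gradient estimator for subset i at x; mutates SAGA's table in place.

    Unbiased by construction: averaging over i = 0..n-1 at fixed x and state
    yields exactly grad J(x) for all three estimators.
    """
    n = state.n
    gi = bundle.subset_gradient(x, i)
    if state.kind == "sgd":
        return n * gi
    if state.kind == "saga":
        if state.grad_table is None or state.grad_table_sum is None:
            raise ValueError("SAGA state not initialized")
        est = n * (gi - state.grad_table[i]) + state.grad_table_sum
        state.grad_table_sum = state.grad_table_sum - state.grad_table[i] + gi
        state.grad_table[i] = gi
        return est
    # svrg
    if state.snapshot is None or state.full_gradient is None:
        raise ValueError("SVRG state not initialized")
    gi_hat = bundle.subset_gradient(state.snapshot, i)
    return n * (gi - gi_hat) + state.full_gradient


def apply_update(
    x: np.ndarray, tau: float, diag: np.ndarray, grad: np.ndarray
) -> np.ndarray:
    """One preconditioned proximal step: prox_{>=0}(x - tau * diag * grad)."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if np.any(diag < 0):
        raise ValueError("preconditioner diagonal must be >= 0")
    return prox_nonneg(x - tau * diag * grad)


# --------------------------------------------------------------------------
# OSEM initialization
# --------------------------------------------------------------------------

def osem_init(
    bundle: ObjectiveBundle,
    n_init: int | None = None,
    epochs: int = 1,
    x0: np.ndarray | None = None,
) -> np.ndarray:
    """Ordered-subsets EM sweeps used to initialize the stochastic solvers.

    One epoch is one pass over the ``n_init`` interleaved view subsets in
    natural order (default: the bundle's own partition); the classical
    multiplicative update keeps iterates nonnegative and leaves any exact
    noise-free fit unchanged.  Voxels with zero subset sensitivity are frozen.
    """
    model = bundle.model
    if n_init is None or n_init == bundle.n_subsets:
        subs = [bundle.subset(i) for i in range(bundle.n_subsets)]
        ys = bundle._ys
        rs = bundle._rs
    else:
        scheme = partition_views(model.geom.n_views, n_init)
        subs = [model.subset_model(v) for v in scheme.view_lists]
        ys = [m.extract(bundle.y) for m in subs]
        rs = [m.extract(bundle.r) for m in subs]

    x = np.ones(model.grid.shape) if x0 is None else x0.astype(float).copy()
    for _ in range(epochs):
        for m, yi, ri in zip(subs, ys, rs):
            ax = m.forward(x) + ri
            ratio = np.ones_like(ax)
            pos = ax > 0
            ratio[pos] = yi[pos] / ax[pos]
            back = m.adjoint(ratio)
            sens = m.sensitivity
            mult = np.ones_like(x)
            fov = sens > 0
            mult[fov] = back[fov] / sens[fov]
            x = x * mult
    return x


# --------------------------------------------------------------------------
# converged reference
# --------------------------------------------------------------------------

def reference_solve(
    bundle: ObjectiveBundle,
    iterations: int = 500,
    x0: np.ndarray | None = None,
    scale: np.ndarray | None = None,
) -> tuple[np.ndarray, dict[str, float]]:
    """Bound-constrained quasi-Newton minimizer of D + beta*S over x >= 0.

    Used as the converged reference for NRMSE.  Variables are rescaled by a
    positive diagonal (default: the harmonic diagonal at the start image),
    which approximates preconditioning, then handed to L-BFGS-B.  Returns
    (x_ref, info) with the final objective and projected-gradient norm.
    """
    if x0 is None:
        x0 = osem_init(bundle)
    val0, _ = bundle.objective(np.maximum(x0, 0))
    if not np.isfinite(val0):
        raise ValueError("objective is not finite at the starting image")

    if scale is None:
        from .precond import harmonic_diag, mlem_diag

        delta = 1e-6 * max(float(x0.max()), 1.0)
        if bundle.rdp.beta > 0:
            scale = harmonic_diag(
                np.maximum(x0, 0), bundle.model.sensitivity, bundle.rdp, delta
            )
        else:
            scale = mlem_diag(np.maximum(x0, 0), bundle.model.sensitivity, delta)
    c = np.sqrt(np.maximum(np.asarray(scale, dtype=float), 1e-12 * scale.max()))
    shape = bundle.model.grid.shape

    def fun(z: np.ndarray) -> tuple[float, np.ndarray]:
        x = np.maximum(c * z.reshape(shape), 0.0)
        v, g = bundle.objective(x)
        return v, (c * g).ravel()

    res = scipy.optimize.minimize(
        fun,
        (x0 / c).ravel(),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0, None)] * x0.size,
        options={"maxiter": iterations, "maxfun": 10 * iterations, "ftol": 1e-15, "gtol": 1e-10},
    )
    x_ref = np.maximum(c * res.x.reshape(shape), 0.0)
    val, grad = bundle.objective(x_ref)
    pg = np.where((x_ref <= 0) & (grad > 0), 0.0, grad)
    info = {
        "objective": float(val),
        "projected_gradient_norm": float(np.linalg.norm(pg)),
        "n_iterations": float(res.nit),
    }
    return x_ref, info


# --------------------------------------------------------------------------
# configuration and presets
# --------------------------------------------------------------------------

@dataclass
class ReconConfig:
    """Full reconstruction recipe; a run is reproducible from (config, dataset)."""

    estimator: str = "svrg"
    preconditioner: str = "harmonic"
    precond_update_epochs: tuple[int, ...] = (1, 2, 3)
    precond_delta_rel: float = 1e-6
    precond_alpha: float = 1.0
    stepsize: StepsizeRule = field(default_factory=StepsizeRule)
    sampler: str = "without_replacement"
    fixed_permutation: bool = False
    n_subsets: int | None = None
    subset_target: float = 25.0
    epochs: int = 100
    beta: float | None = None
    beta_rel: float | None = None
    gamma: float = 2.0
    epsilon: float | None = None  # None -> 1e-3 x mean nonzero of the init image
    kappa: np.ndarray | None = None
    omega: int = 2
    osem_subsets: int = 27
    osem_epochs: int = 1
    bb_epochs: tuple[int, ...] = ()
    seed: int = 0
    preset: str = "custom"

    def resolve_beta(self, true_counts: float) -> float:
        if self.beta is not None:
            return self.beta
        if self.beta_rel is not None:
            return beta_from_relative(self.beta_rel, true_counts)
        raise ValueError("either beta or beta_rel must be set")


def preset_config(name: str, **overrides: Any) -> ReconConfig:
    """The three submitted-algorithm presets.

    All use SVRG with the harmonic-mean preconditioner; they differ only in
    subset count target, subset order, preconditioner update epochs and
    stepsize rule.
    """
    name = name.lower()
    if name == "alg1":
        cfg = ReconConfig(
            estimator="svrg",
            preconditioner="harmonic",
            precond_update_epochs=(1, 2, 3),
            sampler="without_replacement",
            fixed_permutation=True,
            subset_target=25.0,
            stepsize=StepsizeRule(kind="alg1_schedule", tau0=3.0),
            preset="alg1",
        )
    elif name == "alg2":
        cfg = ReconConfig(
            estimator="svrg",
            preconditioner="harmonic",
            precond_update_epochs=(1, 2, 4, 6),
            sampler="without_replacement",
            fixed_permutation=True,
            subset_target=25.0,
            stepsize=StepsizeRule(kind="alg23_schedule", tau0=3.0, bb_value=3.0),
            bb_epochs=(2, 4, 6),
            preset="alg2",
        )
    elif name == "alg3":
        cfg = ReconConfig(
            estimator="svrg",
            preconditioner="harmonic",
            precond_update_epochs=(1, 2, 4, 6),
            sampler="cofactor",
            subset_target=24.2,
            stepsize=StepsizeRule(kind="alg23_schedule", tau0=3.0, bb_value=3.0),
            bb_epochs=(2, 4, 6),
            preset="alg3",
        )
    else:
        raise ValueError(f"unknown preset {name!r}")
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise TypeError(f"unknown config field {k!r}")
        setattr(cfg, k, v)
    return cfg


# --------------------------------------------------------------------------
# main loop
# --------------------------------------------------------------------------

def run_reconstruction(
    config: ReconConfig,
    dataset: SimulatedDataset,
    x_ref: np.ndarray | None = None,
    record_updates: bool = False,
) -> tuple[np.ndarray, dict[str, Any]]:
    """OSEM init -> preconditioned stochastic loop; returns (x_final, history).

    ``history`` holds per-epoch lists (epoch, update k, objective, tau, and
    NRMSE against ``x_ref`` over the whole-object mask when a reference is
    given) plus the emitted subset sequence; identical (config, dataset)
    pairs replay bitwise-identically.
    """
    model = dataset.model
    if model is None:
        raise ValueError("dataset has no attached system model")
    n_views = model.geom.n_views
    n = config.n_subsets or choose_num_subsets(n_views, config.subset_target)
    scheme = partition_views(n_views, n)

    beta = config.resolve_beta(dataset.true_counts)

    # OSEM initialization (beta plays no role there)
    init_rdp = RDPParams(beta=0.0, gamma=config.gamma, epsilon=1.0,
                         spacing=model.grid.spacing)
    init_bundle = ObjectiveBundle(model, dataset.y, dataset.r, scheme, init_rdp)
    n_osem = min(config.osem_subsets, n_views)
    x = osem_init(init_bundle, n_init=n_osem, epochs=config.osem_epochs)

    eps = config.epsilon if config.epsilon is not None else epsilon_from_image(x)
    rdp = RDPParams(beta=beta, gamma=config.gamma, epsilon=eps,
                    kappa=config.kappa, spacing=model.grid.spacing)
    bundle = ObjectiveBundle(model, dataset.y, dataset.r, scheme, rdp)

    delta = config.precond_delta_rel * max(float(x.max()), 1e-30)
    pstate = PreconditionerState(
        kind=config.preconditioner,
        delta=delta,
        alpha=config.precond_alpha,
        update_epochs=frozenset(config.precond_update_epochs) or frozenset({1}),
        rdp=rdp,
    )
    pstate = replace(pstate, current_diag=pstate.compute(x, model.sensitivity))

    sampler = SubsetSampler(
        config.sampler, n, seed=config.seed, fixed_permutation=config.fixed_permutation
    )

    if config.estimator == "sgd":
        est = EstimatorState.sgd(n)
    elif config.estimator == "saga":
        est = EstimatorState.saga(bundle, x)
    elif config.estimator == "svrg":
        est = EstimatorState.svrg(bundle, x, omega=config.omega)
        if config.sampler == "importance":
            norms = [
                float(np.linalg.norm(bundle.subset_gradient(x, i))) for i in range(n)
            ]
            sampler.set_probabilities(np.asarray(norms))
    else:
        raise ValueError(f"unknown estimator {config.estimator!r}")

    mask = dataset.masks.get("whole_object")
    stepsize = replace(config.stepsize)
    bb_epochs = set(config.bb_epochs)
    prev_snapshot = est.snapshot.copy() if est.kind == "svrg" else None
    prev_full_grad = est.full_gradient.copy() if est.kind == "svrg" else None

    history: dict[str, Any] = {
        "epoch": [], "update": [], "objective": [], "nrmse": [], "tau": [],
        "subset_sequence": [], "beta": beta, "epsilon": eps, "n_subsets": n,
        "delta": delta,
    }
    if record_updates:
        history["update_tau"] = []

    def record(epoch_idx: int, k: int) -> None:
        val, _ = bundle.objective(x)
        history["epoch"].append(epoch_idx)
        history["update"].append(k)
        history["objective"].append(float(val))
        if x_ref is not None and mask is not None:
            history["nrmse"].append(
                nrmse(x, x_ref, mask, dataset.norm_activity)
            )
        else:
            history["nrmse"].append(np.nan)
        history["tau"].append(stepsize(max(k - 1, 0), n) if k > 0 else np.nan)

    record(0, 0)
    k = 0
    for epoch in range(1, config.epochs + 1):
        pstate = pstate.maybe_update(epoch, x, model.sensitivity)
        for _ in range(n):
            i = sampler.next()
            history["subset_sequence"].append(i)
            grad = estimator_gradient(est, bundle, x, i)
            tau = stepsize(k, n)
            if record_updates:
                history["update_tau"].append(tau)
            x = apply_update(x, tau, pstate.current_diag, grad)
            k += 1
            if est.kind == "svrg":
                est.updates_since_snapshot += 1
                if est.updates_since_snapshot >= est.omega * n:
                    est.refresh_snapshot(bundle, x)
                    epochs_done = k // n + (1 if k % n else 0)
                    if bb_epochs and epochs_done in bb_epochs:
                        p = est.snapshot - prev_snapshot
                        q = est.full_gradient - prev_full_grad
                        qq = float(q.ravel() @ q.ravel())
                        if qq > 0:
                            stepsize.set_bb(bb_short(p, q))
                    prev_snapshot = est.snapshot.copy()
                    prev_full_grad = est.full_gradient.copy()
                    if config.sampler == "importance":
                        norms = [
                            float(np.linalg.norm(bundle.subset_gradient(est.snapshot, j)))
                            for j in range(n)
                        ]
                        sampler.set_probabilities(np.asarray(norms))
        record(epoch, k)

    return x, history
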