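"""Diagonal preconditioners for stochastic PET reconstruction.

Two diagonals are provided: the classic MLEM preconditioner
D_MLEM(x) = (x + delta) / A^T 1, and a prior-aware combination that takes the
scaled harmonic mean of D_MLEM with the inverse diagonal Hessian of the
regularizer beta*S:

    D(x) = (D_MLEM^{-1} + alpha D_betaS^{-1})^{-1}
         = (x + delta) / (A^T 1 + alpha diagH_betaS(x) (x + delta)),

which satisfies D <= min(D_MLEM, alpha^{-1} D_betaS) elementwise.  Because
the RDP Hessian diagonal is large exactly where activity is small, the
harmonic diagonal damps background updates that the MLEM diagonal alone
over-scales under strong regularization.

The diagonal is recomputed only at the start of a configured set of epochs
(it stabilizes after the first few) and is frozen in between.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .objective import RDPParams

__all__ = ["mlem_diag", "harmonic_diag", "PreconditionerState"]


def _check(x: np.ndarray, sensitivity: np.ndarray, delta: float) -> None:
    if delta <= 0:
        raise ValueError("delta must be > 0")
    if np.any(np.asarray(x) < 0):
        raise ValueError("x must be >= 0")
    if np.any(np.asarray(sensitivity) < 0):
        raise ValueError("sensitivity must be >= 0 (0 only outside the FOV)")


def mlem_diag(x: np.ndarray, sensitivity: np.ndarray, delta: float) -> np.ndarray:
    """(x + delta) / A^T 1 elementwise; 0 (frozen) where sensitivity is 0."""
    _check(x, sensitivity, delta)
    out = np.zeros_like(np.asarray(x, dtype=float))
    fov = sensitivity > 0
    out[fov] = (x[fov] + delta) / sensitivity[fov]
    return out


def harmonic_diag(
    x: np.ndarray,
    sensitivity: np.ndarray,
    rdp: RDPParams,
    delta: float,
    alpha: float = 1.0,
) -> np.ndarray:
    """Harmonic-mean diagonal of Eq-above; reduces to mlem_diag when beta = 0."""
    _check(x, sensitivity, delta)
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if rdp.beta == 0 or alpha == 0:
        return mlem_diag(x, sensitivity, delta)
    h = rdp.beta * rdp.diag_hessian(x)
    out = np.zeros_like(np.asarray(x, dtype=float))
    fov = sensitivity > 0
    xp = x[fov] + delta
    out[fov] = xp / (sensitivity[fov] + alpha * h[fov] * xp)
    return out


@dataclass
class PreconditionerState:
    """Diagonal plus its update schedule.

    ``update_epochs`` are 1-based epoch indices (epoch e covers updates
    (e-1)*n .. e*n - 1); the diagonal is recomputed at the *start* of those
    epochs from the current iterate and frozen otherwise.
    """

    kind: str
    delta: float
    alpha: float = 1.0
    update_epochs: frozenset[int] = frozenset({1, 2, 3})
    current_diag: np.ndarray | None = None
    rdp: RDPParams | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ("mlem", "harmonic"):
            raise ValueError(f"unknown preconditioner kind {self.kind!r}")
        if self.kind == "harmonic" and self.rdp is None:
            raise ValueError("harmonic preconditioner requires RDP parameters")
        self.update_epochs = frozenset(self.update_epochs)

    def compute(self, x: np.ndarray, sensitivity: np.ndarray) -> np.ndarray:
        if self.kind == "mlem":
            return mlem_diag(x, sensitivity, self.delta)
        assert self.rdp is not None
        return harmonic_diag(x, sensitivity, self.rdp, self.delta, self.alpha)

    def maybe_update(
        self, epoch: int, x: np.ndarray, sensitivity: np.ndarray
    ) -> "PreconditionerState":
        """Recompute the diagonal iff ``epoch`` (1-based) is scheduled;
        otherwise return the state unchanged."""
        if epoch < 0:
            raise ValueError("epoch must be >= 0")
        if epoch not in self.update_epochs:
            return self
        return replace(self, current_diag=self.compute(x, sensitivity))
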