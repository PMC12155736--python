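"""Subset partitioning, access-order strategies, and stepsize rules.

Five subset-ordering strategies are provided: the deterministic Herman-Meyer
order (mixed-radix digit reversal over the prime factorization of n, which
maximizes angular spread between consecutive subsets), uniform sampling with
and without replacement, importance sampling weighted by subset gradient
norms, and the cofactor order: each epoch traverses the cyclic group Z_n with
a generator g coprime to n, generators ranked by proximity to 0.3n and 0.7n.

Stepsize rules: constant; vanishing tau(k) = tau0 / (1 + eta k / n); the
short-form Barzilai-Borwein step p.q / q.q; and the two piecewise preset
schedules used by the submitted reconstruction algorithms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SubsetScheme",
    "choose_num_subsets",
    "partition_views",
    "herman_meyer_order",
    "cofactor_order",
    "SubsetSampler",
    "bb_short",
    "StepsizeRule",
    "constant_rule",
    "vanishing_rule",
    "alg1_schedule",
    "alg23_schedule",
]


# --------------------------------------------------------------------------
# partitioning
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SubsetScheme:
    """Every-n-th-view partition of the views into n disjoint subsets."""

    n_views: int
    n: int
    view_lists: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        flat = sorted(v for lst in self.view_lists for v in lst)
        if flat != list(range(self.n_views)):
            raise ValueError("view_lists must partition all views")


def choose_num_subsets(n_views: int, target: float) -> int:
    """Divisor of n_views closest to ``target``; ties go to the smaller divisor."""
    if n_views < 1 or target <= 0:
        raise ValueError("n_views >= 1 and target > 0 required")
    divisors = [d for d in range(1, n_views + 1) if n_views % d == 0]
    return min(divisors, key=lambda d: (abs(d - target), d))


def partition_views(n_views: int, n: int) -> SubsetScheme:
    """Subset i gets views {i, i+n, i+2n, ...} (interleaved angular coverage)."""
    if not 1 <= n <= n_views:
        raise ValueError("need 1 <= n <= n_views")
    lists = tuple(tuple(range(i, n_views, n)) for i in range(n))
    return SubsetScheme(n_views=n_views, n=n, view_lists=lists)


# --------------------------------------------------------------------------
# deterministic orders
# --------------------------------------------------------------------------

def _prime_factors(n: int) -> list[int]:
    out, p = [], 2
    while p * p <= n:
        while n % p == 0:
            out.append(p)
            n //= p
        p += 1
    if n > 1:
        out.append(n)
    return out


def herman_meyer_order(n: int) -> list[int]:
    """Herman-Meyer access order: digit reversal in the mixed radix given by
    the ascending prime factorization of n (bit reversal when n is a power
    of 2).  Always a permutation of 0..n-1."""
    if n < 1:
        raise ValueError("n must be >= 1")
    factors = _prime_factors(n)
    order = []
    for i in range(n):
        rem, digits = i, []
        for f in factors:
            digits.append(rem % f)
            rem //= f
        # reversed significance: the least significant digit of i becomes
        # the most significant digit of the emitted index
        val, mult = 0, n
        for d, f in zip(digits, factors):
            mult //= f
            val += d * mult
        order.append(val)
    return order


def cofactor_order(n: int, epoch: int) -> list[int]:
    """Cyclic-group traversal order for one epoch.

    Generators k (1 <= k < n, gcd(k, n) = 1) are ranked ascending by
    min(|k - 0.3 n|, |k - 0.7 n|), ties broken by smaller k; epoch e uses
    generator ranked[e mod count] and emits (0, g, 2g, ...) mod n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        return [0]
    gens = [k for k in range(1, n) if math.gcd(k, n) == 1]
    gens.sort(key=lambda k: (min(abs(k - 0.3 * n), abs(k - 0.7 * n)), k))
    g = gens[epoch % len(gens)]
    return [(j * g) % n for j in range(n)]


# --------------------------------------------------------------------------
# sampler
# --------------------------------------------------------------------------

_RULES = ("herman_meyer", "with_replacement", "without_replacement", "importance", "cofactor")


class SubsetSampler:
    """Stateful subset-index source; deterministic given (rule, seed).

    ``without_replacement`` draws a fresh permutation each epoch unless
    ``fixed_permutation=True``, in which case one seeded permutation is drawn
    once and reused every epoch (the "fixed random sequence" mode).
    ``importance`` draws i.i.d. from ``probabilities``, which callers refresh
    (e.g. from subset-gradient norms at snapshot points); probabilities are
    floored at 0.1/n and renormalized to avoid starving subsets.
    """

    def __init__(
        self,
        rule: str,
        n: int,
        seed: int = 0,
        fixed_permutation: bool = False,
    ):
        if rule not in _RULES:
            raise ValueError(f"unknown sampler rule {rule!r}")
        if n < 1:
            raise ValueError("n must be >= 1")
        self.rule = rule
        self.n = n
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.position = 0
        self.epoch = 0
        self.probabilities: np.ndarray | None = None
        self._fixed = fixed_permutation
        self._order: list[int] | None = None
        if rule == "herman_meyer":
            self._order = herman_meyer_order(n)
        elif rule == "without_replacement" and fixed_permutation:
            self._order = list(self.rng.permutation(n))

    def set_probabilities(self, p: np.ndarray) -> None:
        p = np.asarray(p, dtype=float)
        if p.shape != (self.n,) or np.any(p < 0) or p.sum() <= 0:
            raise ValueError("probabilities must be a nonnegative vector of length n")
        p = p / p.sum()
        p = np.maximum(p, 0.1 / self.n)
        self.probabilities = p / p.sum()

    def next(self) -> int:
        """Next subset index; advances epoch bookkeeping every n draws."""
        if self.rule == "with_replacement":
            idx = int(self.rng.integers(self.n))
        elif self.rule == "importance":
            if self.probabilities is None:
                raise ValueError("importance sampler has no probabilities set")
            idx = int(self.rng.choice(self.n, p=self.probabilities))
        else:
            if self.position == 0:
                if self.rule == "cofactor":
                    self._order = cofactor_order(self.n, self.epoch)
                elif self.rule == "without_replacement" and not self._fixed:
                    self._order = list(self.rng.permutation(self.n))
            assert self._order is not None
            idx = int(self._order[self.position])
        self.position += 1
        if self.position == self.n:
            self.position = 0
            self.epoch += 1
        return idx


# --------------------------------------------------------------------------
# stepsizes
# --------------------------------------------------------------------------

def bb_short(p: np.ndarray, q: np.ndarray) -> float:
    """Short-form Barzilai-Borwein step p.q / q.q (plain Euclidean products).

    ``p`` is the iterate difference, ``q`` the gradient difference.  Callers
    keep the previous stepsize when the result is nonpositive.
    """
    p = np.asarray(p, dtype=float).ravel()
    q = np.asarray(q, dtype=float).ravel()
    qq = float(q @ q)
    if qq == 0.0:
        raise ValueError("bb_short requires a nonzero gradient difference")
    return float(p @ q) / qq


@dataclass
class StepsizeRule:
    """Stepsize tau(k) as a function of the update index k.

    kinds: ``constant`` tau0; ``vanishing`` tau0 / (1 + eta k / n);
    ``alg1_schedule`` the fixed piecewise schedule 3, 2, 1.5, 1, 0.5 with
    breakpoints at k = 10, 100, 200, 300; ``alg23_schedule``
    min(tau_bb, cap(k)) with caps 3 (k < 10), 2.2 (10 <= k < 2n), 1 (k >= 2n),
    where tau_bb is refreshed externally via ``set_bb``.
    """

    kind: str = "vanishing"
    tau0: float = 1.0
    eta: float = 0.02
    bb_value: float | None = None
    breakpoints: tuple[tuple[int, float], ...] = field(default=())

    _ALG1 = ((0, 3.0), (10, 2.0), (100, 1.5), (200, 1.0), (300, 0.5))

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "vanishing", "alg1_schedule", "alg23_schedule"):
            raise ValueError(f"unknown stepsize kind {self.kind!r}")
        if self.tau0 <= 0:
            raise ValueError("tau0 must be > 0")

    def set_bb(self, value: float) -> None:
        """Install a freshly computed BB step; nonpositive values are ignored
        (negative-curvature guard keeps the previous step)."""
        if value > 0:
            self.bb_value = float(value)

    def __call__(self, k: int, n: int) -> float:
        if k < 0:
            raise ValueError("update index must be >= 0")
        if self.kind == "constant":
            return self.tau0
        if self.kind == "vanishing":
            return self.tau0 / (1.0 + self.eta * k / n)
        if self.kind == "alg1_schedule":
            table = self.breakpoints or self._ALG1
            tau = table[0][1]
            for k0, v in table:
                if k >= k0:
                    tau = v
            return tau
        # alg23_schedule
        if self.bb_value is None:
            raise ValueError("alg23_schedule requires a BB value (call set_bb first)")
        if k < 10:
            cap = 3.0
        elif k < 2 * n:
            cap = 2.2
        else:
            cap = 1.0
        return min(self.bb_value, cap)
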