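"""Closed-form expectations over uniformly distributed, ordered inputs.

The normalized spike times ``X = T/lam`` of a sorted uniform train are order
statistics of n i.i.d. uniforms, so the k-th one is Beta(k, n-k+1).  The
closed forms below treat the order statistics as *independent* Beta marginals
(the method's central approximation) and truncate the exponential decay
factors by a Taylor series in ``lam/tau``:

    E[exp(+c X_i)] ~ A_i = sum_{h=0}^{q} c^h mu_h(i) / h!
    E[exp(-c X_k)] ~ B_k = sum_{h=0}^{q} (-c)^h mu_h(k) / h!

with ``c = lam/tau`` and ``mu_h(k) = prod_{r<h} (k+r)/(n+1+r)`` the raw Beta
moments.  ``q=None`` requests the exact marginal expectation, the confluent
hypergeometric function 1F1(k; n+1; +-c).  The truncation order ``q`` counts
powers kept (terms h = 0..q); the default q=3 keeps cubic terms.

The expected potential at the k-th input (all decay factors grouped per
index, the i=k term contributing exactly ``w_k``) is

    E[u_k] = sum_{i<k} w_i A_i B_k + w_k,

and the expected potential difference produced by delays ``dt_i >= 0`` is

    E[du_m] = sum_{i<m} w_i D_i B_m + w_m (e^{dt_m/tau} - 1),

where ``D_i`` truncates ``(e^{dt_i/tau} - 1) e^{c X_i}`` to total degree q
and the final (boundary) term is input-independent.  ``boundary=False``
drops it, matching the shortest printed variant of the formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import hyp1f1
from scipy.stats import beta as beta_dist

from .errors import NoPredecessorError, NotFiredInExpectationError
from .types import NeuronParams, Perturbation

__all__ = [
    "ApproxOrders",
    "ExpectationContext",
    "beta_marginal_density",
    "beta_order_moment",
    "exp_moment_series",
    "expected_potential",
    "select_m",
    "select_j",
    "expected_potential_difference",
]


@dataclass(frozen=True)
class ApproxOrders:
    """Truncation orders of the two series approximations.

    ``p`` is the order of the geometric expansion of the reciprocal
    denominator (terms r = 0..p of ``1/(1+x) ~ sum (-x)^r``); ``q`` the order
    of the exponential Taylor truncation (powers kept, h = 0..q).  ``None``
    selects the exact limit (true reciprocal / hypergeometric moment).
    """

    p: Optional[int] = 1
    q: Optional[int] = 3

    def __post_init__(self):
        for name, v in (("p", self.p), ("q", self.q)):
            if v is not None and (not isinstance(v, (int, np.integer)) or v < 1):
                raise ValueError(f"{name} must be a positive integer or None, got {v!r}")


@dataclass(frozen=True)
class ExpectationContext:
    """Everything the closed forms need: neuron parameters, window length,
    and the approximation orders."""

    params: NeuronParams
    lam: float
    approx: ApproxOrders = field(default_factory=ApproxOrders)

    def __post_init__(self):
        if not self.lam > 0:
            raise ValueError(f"lam must be positive, got {self.lam}")

    @property
    def n(self) -> int:
        return self.params.n

    @property
    def decay_ratio(self) -> float:
        """lam/tau, the expansion variable of the Taylor truncations."""
        return self.lam / self.params.tau


def beta_marginal_density(k: int, n: int, x) -> np.ndarray | float:
    """Density of the k-th of n sorted uniforms: Beta(k, n-k+1)."""
    if not 1 <= k <= n:
        raise ValueError(f"k = {k} out of range 1..{n}")
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("x must lie in [0, 1]")
    out = beta_dist.pdf(x, k, n - k + 1)
    return float(out) if out.ndim == 0 else out


def beta_order_moment(k: int, n: int, h: int) -> float:
    """Raw moment E[X_(k)^h] = prod_{r<h} (k+r)/(n+1+r)."""
    out = 1.0
    for r in range(h):
        out *= (k + r) / (n + 1 + r)
    return out


def _moment_table(n: int, q: int) -> np.ndarray:
    """mu[h, k-1] = E[X_(k)^h] for h = 0..q, k = 1..n."""
    k = np.arange(1, n + 1, dtype=float)
    mu = np.empty((q + 1, n))
    mu[0] = 1.0
    for h in range(1, q + 1):
        mu[h] = mu[h - 1] * (k + h - 1) / (n + h)
    return mu


def exp_moment_series(n: int, c: float, q: Optional[int]) -> np.ndarray:
    """Array over k = 1..n of the (truncated) expectation E[exp(c X_(k))].

    ``q=None`` returns the exact value 1F1(k; n+1; c).
    """
    k = np.arange(1, n + 1)
    if q is None:
        return hyp1f1(k, n + 1, c)
    mu = _moment_table(n, q)
    coef = np.array([c**h / math.factorial(h) for h in range(q + 1)])
    return coef @ mu


def _perturbation_series(ctx: ExpectationContext, deltas: np.ndarray) -> np.ndarray:
    """Array over i = 1..n of D_i, the truncation of
    ``E[(exp(dt_i/tau) - 1) exp(c X_i)]`` to total degree q (q=None exact)."""
    n, q = ctx.n, ctx.approx.q
    c = ctx.decay_ratio
    r = deltas / ctx.params.tau
    if q is None:
        return np.expm1(r) * exp_moment_series(n, c, None)
    mu = _moment_table(n, q)
    out = np.zeros(n)
    for a in range(1, q + 1):
        inner = np.zeros(n)
        for b in range(0, q - a + 1):
            inner += c**b / math.factorial(b) * mu[b]
        out += r**a / math.factorial(a) * inner
    return out


def _expm1_series(x: float, q: Optional[int]) -> float:
    """exp(x) - 1 truncated at degree q (q=None exact)."""
    if q is None:
        return float(np.expm1(x))
    return sum(x**a / math.factorial(a) for a in range(1, q + 1))


def expected_potential(ctx: ExpectationContext, j: int) -> float:
    """Closed-form expectation of the membrane potential at the j-th input,
    ``sum_{i<j} w_i A_i B_j + w_j`` (1-based j)."""
    n = ctx.n
    if not 1 <= j <= n:
        raise ValueError(f"j = {j} out of range 1..{n}")
    w, q, c = ctx.params.weights, ctx.approx.q, ctx.decay_ratio
    A = exp_moment_series(n, c, q)
    B = exp_moment_series(n, -c, q)
    return float(np.sum(w[: j - 1] * A[: j - 1]) * B[j - 1] + w[j - 1])


def _expected_potential_profile(ctx: ExpectationContext) -> np.ndarray:
    """E[u_k] for every k = 1..n (vectorized form of expected_potential)."""
    w, q, c = ctx.params.weights, ctx.approx.q, ctx.decay_ratio
    A = exp_moment_series(ctx.n, c, q)
    B = exp_moment_series(ctx.n, -c, q)
    csum = np.concatenate(([0.0], np.cumsum(w * A)[:-1]))  # sum_{i<k} w_i A_i
    return csum * B + w


def select_m(ctx: ExpectationContext) -> int:
    """Smallest index whose expected potential reaches the threshold — the
    event-driven firing rule applied to the expected trajectory."""
    prof = _expected_potential_profile(ctx)
    hits = np.nonzero(prof >= ctx.params.theta)[0]
    if hits.size == 0:
        raise NotFiredInExpectationError(
            f"no index has expected potential >= theta = {ctx.params.theta:g} "
            f"(max is {prof.max():g})"
        )
    return int(hits[0]) + 1


def select_j(ctx: ExpectationContext, m: int) -> int:
    """Index of the maximum expected potential before ``m``; ties broken
    toward the larger index."""
    if m < 2:
        raise NoPredecessorError("m = 1: no pre-firing index exists")
    if m > ctx.n:
        raise ValueError(f"m = {m} exceeds n = {ctx.n}")
    prof = _expected_potential_profile(ctx)[: m - 1]
    return int(len(prof) - 1 - np.argmax(prof[::-1])) + 1


def expected_potential_difference(
    ctx: ExpectationContext, pert: Perturbation, m: int, *, boundary: bool = True
) -> float:
    """Closed-form E[du_m], the canonical scalar measure of perturbation
    magnitude.

    ``boundary=True`` (default) keeps the input-independent i=m term
    ``w_m (e^{dt_m/tau} - 1)``; ``boundary=False`` reproduces the shorter
    printed variant that stops the sum at m-1.
    """
    n = ctx.n
    if not 1 <= m <= n:
        raise ValueError(f"m = {m} out of range 1..{n}")
    pert.require_length(n)
    pert.require_nonnegative()
    w, q, c = ctx.params.weights, ctx.approx.q, ctx.decay_ratio
    D = _perturbation_series(ctx, pert.deltas)
    B = exp_moment_series(n, -c, q)
    total = float(np.sum(w[: m - 1] * D[: m - 1]) * B[m - 1])
    if boundary:
        total += w[m - 1] * _expm1_series(pert.deltas[m - 1] / ctx.params.tau, q)
    return total
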