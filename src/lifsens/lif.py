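"""Event-driven LIF dynamics under time-to-first-spike coding.

The membrane potential of a neuron receiving weighted input spikes is

    u(t) = sum_{i : t_i <= t} w_i exp(-(t - t_i) / tau),

with resting potential 0.  Between input events the potential strictly
decays, so the first threshold crossing can only occur *at* an input time and
is found by scanning events in order.  The desired firing time interpolates
the potential linearly between the pre-firing maximum and the crossing event,
which makes the output time a continuous function of the perturbation.

Three notions of output deviation coexist:

``exact``
    Recompute the full firing solution on the shifted train ``t + dt`` (same
    weight-spike association, no re-sorting).  This includes the direct
    translation of every event time.
``potential``
    Keep the event clock at the unperturbed times and perturb only the decay
    algebra: the potential at event k becomes
    ``sum_{i<=k} w_i exp(-(t_k - t_i - dt_i)/tau)``, which is the model the
    linearization is built on.  Equivalently, boost each weight by
    ``exp(dt_i/tau)`` and solve the unperturbed train.
``linearized``
    The first-order expression ``(t_m - t_j)/(u_m - u_j) * du_j`` with
    ``du_j`` the algebraic potential difference at ``t_j``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .errors import NoPredecessorError, NotFiredError, SampleExcludedError
from .types import FiringSolution, NeuronParams, Perturbation, SpikeTrain

__all__ = [
    "membrane_potential_at",
    "actual_firing",
    "max_before_firing",
    "desired_firing_time",
    "potential_difference",
    "output_deviation_exact",
    "output_deviation_linearized",
    "BatchSolutions",
    "prefix_potentials",
    "solve_batch",
]


def membrane_potential_at(train: SpikeTrain, params: NeuronParams, t: float) -> float:
    """Membrane potential at time ``t`` (0 if no spike has arrived yet)."""
    times = train.times
    mask = times <= t
    if not mask.any():
        return 0.0
    return float(np.sum(params.weights[mask] * np.exp(-(t - times[mask]) / params.tau)))


def prefix_potentials(times: np.ndarray, weights: np.ndarray, tau: float) -> np.ndarray:
    """Potential at each event using the index-prefix convention.

    ``P[..., k] = sum_{i<=k} w_i exp(-(t_k - t_i)/tau)`` computed by the
    recursion ``P_k = P_{k-1} exp(-(t_k - t_{k-1})/tau) + w_k``, which is an
    algebraic identity valid for *any* ordering of the times (needed for
    perturbed trains that are deliberately not re-sorted).

    ``times`` may be ``(n,)`` or batched ``(S, n)``; ``weights`` broadcasts.
    """
    times = np.atleast_2d(np.asarray(times, dtype=float))
    weights = np.broadcast_to(np.asarray(weights, dtype=float), times.shape)
    P = np.empty_like(times)
    P[:, 0] = weights[:, 0]
    for k in range(1, times.shape[1]):
        P[:, k] = P[:, k - 1] * np.exp(-(times[:, k] - times[:, k - 1]) / tau) + weights[:, k]
    return P


@dataclass
class BatchSolutions:
    """Vectorized firing solutions for a batch of trains.

    Index arrays are 0-based internally; entries of non-firing samples are
    undefined and must be masked with ``fired``.  ``t_d`` follows the m=1
    convention (output time equals the first event time).
    """

    fired: np.ndarray      # (S,) bool
    m_idx: np.ndarray      # (S,) int, 0-based
    j_idx: np.ndarray      # (S,) int, 0-based; -1 where m_idx == 0
    t_m: np.ndarray
    u_m: np.ndarray
    t_j: np.ndarray
    u_j: np.ndarray
    t_d: np.ndarray


def solve_batch(times: np.ndarray, weights: np.ndarray, tau: float, theta: float) -> BatchSolutions:
    """First-crossing scan, pre-firing maximum and desired firing time for a
    batch of trains (rows of ``times``)."""
    times = np.atleast_2d(np.asarray(times, dtype=float))
    S, n = times.shape
    P = prefix_potentials(times, weights, tau)
    crossed = P >= theta
    fired = crossed.any(axis=1)
    m_idx = np.argmax(crossed, axis=1)  # first True; 0 where never fired (masked)

    # argmax over k < m with ties broken toward the larger index: scan the
    # reversed masked row so argmax picks the last maximal position.
    below = np.where(np.arange(n)[None, :] < m_idx[:, None], P, -np.inf)
    j_idx = n - 1 - np.argmax(below[:, ::-1], axis=1)
    j_idx = np.where(m_idx == 0, -1, j_idx)

    take = lambda arr, idx: np.take_along_axis(arr, np.maximum(idx, 0)[:, None], axis=1)[:, 0]
    t_m, u_m = take(times, m_idx), take(P, m_idx)
    t_j, u_j = take(times, j_idx), take(P, j_idx)

    with np.errstate(invalid="ignore", divide="ignore"):
        interp = t_j + (theta - u_j) * (t_m - t_j) / (u_m - u_j)
    t_d = np.where(m_idx == 0, t_m, interp)
    bad = m_idx == 0
    t_j = np.where(bad, np.nan, t_j)
    u_j = np.where(bad, np.nan, u_j)
    return BatchSolutions(fired, m_idx, j_idx, t_m, u_m, t_j, u_j, t_d)


def _solve_single(times: np.ndarray, params: NeuronParams) -> FiringSolution:
    sol = solve_batch(times[None, :], params.weights, params.tau, params.theta)
    if not sol.fired[0]:
        return FiringSolution(fired=False)
    m0 = int(sol.m_idx[0])
    if m0 == 0:
        return FiringSolution(
            fired=True, m=1, t_m=float(sol.t_m[0]), u_m=float(sol.u_m[0]),
            t_d=float(sol.t_d[0]), degenerate=True,
        )
    return FiringSolution(
        fired=True, m=m0 + 1, t_m=float(sol.t_m[0]), u_m=float(sol.u_m[0]),
        j=int(sol.j_idx[0]) + 1, t_j=float(sol.t_j[0]), u_j=float(sol.u_j[0]),
        t_d=float(sol.t_d[0]),
    )


def actual_firing(train: SpikeTrain, params: NeuronParams) -> Optional[Tuple[int, float, float]]:
    """First threshold crossing ``(m, t_m, u_m)`` (1-based m), or None."""
    sol = _solve_single(train.times, params)
    if not sol.fired:
        return None
    return sol.m, sol.t_m, sol.u_m


def max_before_firing(train: SpikeTrain, params: NeuronParams, m: int) -> Tuple[int, float, float]:
    """Index (1-based), time and potential of the pre-firing maximum.

    Ties are broken toward the larger index, i.e. the moment closest to the
    firing event, which keeps the interpolation interval as local as possible.
    """
    if m < 2:
        raise NoPredecessorError("m = 1: no pre-firing moment exists")
    if m > train.n:
        raise ValueError(f"m = {m} exceeds train length {train.n}")
    P = prefix_potentials(train.times, params.weights, params.tau)[0]
    pre = P[: m - 1]
    j0 = int(len(pre) - 1 - np.argmax(pre[::-1]))
    return j0 + 1, float(train.times[j0]), float(P[j0])


def desired_firing_time(train: SpikeTrain, params: NeuronParams) -> FiringSolution:
    """Full firing solution with the interpolated threshold-crossing time.

    Raises :class:`NotFiredError` if the train never reaches threshold.  For
    a crossing at the very first input the solution is flagged degenerate and
    ``t_d`` is that input time.
    """
    sol = _solve_single(train.times, params)
    if not sol.fired:
        raise NotFiredError("membrane potential never reaches threshold")
    return sol


def potential_difference(
    train: SpikeTrain, pert: Perturbation, params: NeuronParams, t: float, k: int
) -> float:
    """Algebraic perturbed-minus-unperturbed potential of the first ``k``
    inputs, evaluated at time ``t``:

        sum_{i<=k} w_i [exp(-(t - t_i - dt_i)/tau) - exp(-(t - t_i)/tau)]
    """
    if not 1 <= k <= train.n:
        raise ValueError(f"k = {k} out of range 1..{train.n}")
    pert.require_length(train.n)
    ts, dts, w = train.times[:k], pert.deltas[:k], params.weights[:k]
    tau = params.tau
    return float(np.sum(w * (np.exp(-(t - ts - dts) / tau) - np.exp(-(t - ts) / tau))))


def output_deviation_exact(
    train: SpikeTrain,
    pert: Perturbation,
    params: NeuronParams,
    mode: str = "exact",
) -> float:
    """|t_d' - t_d| with the perturbed solution fully recomputed.

    ``mode="exact"`` recomputes on the shifted train ``t + dt`` (events move;
    the weight-spike association is fixed at the unperturbed ordering and the
    train is not re-sorted).  ``mode="potential"`` keeps the event clock at
    the unperturbed times and applies the algebraic potential perturbation
    only, implemented as the weight boost ``w_i -> w_i exp(dt_i/tau)``.

    Raises :class:`SampleExcludedError` if either solution does not fire.
    """
    pert.require_length(train.n)
    base = _solve_single(train.times, params)
    if not base.fired:
        raise SampleExcludedError("unperturbed train does not fire")
    if mode == "exact":
        sol = _solve_single(train.times + pert.deltas, params)
    elif mode == "potential":
        boosted = NeuronParams(
            params.weights * np.exp(pert.deltas / params.tau), params.tau, params.theta
        )
        sol = _solve_single(train.times, boosted)
    else:
        raise ValueError(f"unknown mode {mode!r} (use 'exact' or 'potential')")
    if not sol.fired:
        raise SampleExcludedError("perturbed train does not fire")
    return abs(sol.t_d - base.t_d)


def output_deviation_linearized(
    train: SpikeTrain, pert: Perturbation, params: NeuronParams
) -> float:
    """First-order output deviation ``(t_m - t_j)/(u_m - u_j) * du_j`` with
    ``(j, m)`` taken from the unperturbed solution.

    For a crossing at the first input (no predecessor) the output time is
    that input time, so the deviation is ``|dt_1|``.
    """
    pert.require_length(train.n)
    base = _solve_single(train.times, params)
    if not base.fired:
        raise NotFiredError("train does not fire")
    if base.degenerate:
        return abs(float(pert.deltas[0]))
    du_j = potential_difference(train, pert, params, base.t_j, base.j)
    return (base.t_m - base.t_j) / (base.u_m - base.u_j) * du_j
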