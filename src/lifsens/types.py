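"""Core data containers for LIF sensitivity analysis.

Conventions shared by the whole package:

* Spike times live on the encoding window ``[0, lam]`` where ``lam`` (the
  "number of time steps" of the coding scheme) acts purely as a length
  scale: dividing a
  uniformly distributed train by ``lam`` gives sorted uniforms on ``[0, 1]``.
* Indices ``i, j, m`` into a train are **1-based** in every public interface,
  matching the standard order-statistic notation ``X_(k) ~ Beta(k, n-k+1)``.
* The resting potential is 0 and synaptic weights are expressed directly in
  potential units (any membrane resistance/charge factors are absorbed into
  the weights).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


def _as_1d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size < 1:
        raise ValueError(f"{name} must have at least one element")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class NeuronParams:
    """Parameters of a single LIF neuron.

    Parameters
    ----------
    weights
        Synaptic efficacies ``w_1 .. w_n`` (potential units), index-aligned
        with the input spike train.
    tau
        Membrane time constant, in the same time unit as the spike times
        (milliseconds throughout the examples).
    theta
        Firing threshold (potential units).
    """

    weights: np.ndarray
    tau: float
    theta: float

    def __post_init__(self):
        object.__setattr__(self, "weights", _as_1d_float(self.weights, "weights"))
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if not self.theta > 0:
            raise ValueError(f"theta must be positive, got {self.theta}")

    @property
    def n(self) -> int:
        return self.weights.size

    def require_nonnegative_weights(self) -> None:
        """The analytic (closed-form) path assumes weights sampled on [0, 1]."""
        if np.any(self.weights < 0):
            raise ValueError("closed-form sensitivity requires nonnegative weights")


@dataclass(frozen=True)
class SpikeTrain:
    """An ordered input spike train on the encoding window ``[0, lam]``."""

    times: np.ndarray
    lam: float

    def __post_init__(self):
        object.__setattr__(self, "times", _as_1d_float(self.times, "times"))
        if not self.lam > 0:
            raise ValueError(f"lam must be positive, got {self.lam}")
        t = self.times
        if np.any(np.diff(t) < 0):
            raise ValueError("spike times must be nondecreasing")
        if t[0] < 0 or t[-1] > self.lam:
            raise ValueError("spike times must lie within [0, lam]")

    @property
    def n(self) -> int:
        return self.times.size

    @staticmethod
    def sorted_uniform(n: int, lam: float, rng: np.random.Generator) -> "SpikeTrain":
        """Draw n i.i.d. uniform times on [0, lam] and sort them."""
        return SpikeTrain(np.sort(rng.uniform(0.0, lam, n)), lam)


@dataclass(frozen=True)
class Perturbation:
    """Per-input time deviations, index-aligned with a spike train.

    The closed-form path requires all entries to be nonnegative (delays);
    Monte-Carlo estimation accepts arbitrary signs.
    """

    deltas: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "deltas", _as_1d_float(self.deltas, "deltas"))

    @property
    def n(self) -> int:
        return self.deltas.size

    @staticmethod
    def zero(n: int) -> "Perturbation":
        return Perturbation(np.zeros(n))

    def scaled(self, c: float) -> "Perturbation":
        return Perturbation(c * self.deltas)

    def require_nonnegative(self) -> None:
        if np.any(self.deltas < 0):
            raise ValueError("the analytic path requires nonnegative perturbations")

    def require_length(self, n: int) -> None:
        if self.n != n:
            raise ValueError(f"perturbation has length {self.n}, expected {n}")


@dataclass(frozen=True)
class FiringSolution:
    """Threshold crossing of one concrete train, with the interpolated
    (desired) firing time.

    ``m`` is the 1-based index of the input at which the potential first
    reaches threshold; ``j`` the 1-based index of the maximum-potential moment
    before it (ties broken toward the larger index).  The desired firing time
    interpolates linearly between ``(t_j, u_j)`` and ``(t_m, u_m)``:

        t_d = t_j + (theta - u_j) (t_m - t_j) / (u_m - u_j)

    When ``m == 1`` there is no pre-firing moment; by convention the output
    time is the first input time itself (``t_d = t_m``, ``degenerate=True``).
    """

    fired: bool
    m: Optional[int] = None
    t_m: float = float("nan")
    u_m: float = float("nan")
    j: Optional[int] = None
    t_j: float = float("nan")
    u_j: float = float("nan")
    t_d: float = float("nan")
    degenerate: bool = field(default=False)
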