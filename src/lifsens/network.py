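"""Layer and network sensitivity for fully connected feedforward SNNs.

The sensitivity of a layer is the vector of its neurons' sensitivities; the
sensitivity of the network is that of its output layer, computed layer by
layer with each layer's sensitivity vector fed to the next layer as its
input perturbation.  The closed-form path applies the per-neuron analytic
formula with the synapse index treated as order-statistic index — the same
uniform-input assumption at every layer, a known model approximation since
hidden-layer spike times are not uniform.

The Monte-Carlo baseline forward-propagates actual spike trains: each
neuron's output time is its desired firing time given its inputs (an option
switches to actual firing times), and the per-sample deviation compares the
unperturbed and perturbed copies of the whole network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np

from .errors import EstimationUnreliableError, LifsensError
from .lif import solve_batch
from .orderstats import ApproxOrders, ExpectationContext
from .sensitivity import MCConfig, SensitivityResult, neuron_sensitivity_closed_form
from .types import NeuronParams, Perturbation

__all__ = ["NetworkSpec", "LayerSensitivity", "layer_sensitivity", "snn_sensitivity",
           "network_mc_sensitivity"]

ScalarOrPerLayer = Union[float, Sequence[float]]


@dataclass(frozen=True)
class LayerSensitivity:
    """Per-neuron sensitivity vector of one layer."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("layer sensitivity must be a vector")
        if np.any(v < 0):
            raise ValueError("sensitivities must be nonnegative")
        object.__setattr__(self, "values", v)

    def as_perturbation(self) -> Perturbation:
        return Perturbation(self.values)


@dataclass(frozen=True)
class NetworkSpec:
    """Topology and parameters of a fully connected feedforward SNN.

    ``layer_sizes`` is ``(n0, n1, ..., nL)`` including the input layer.
    ``weights[l]`` is the ``(n_{l+1}, n_l)`` matrix of layer l+1 (one weight
    row per neuron).  ``tau``, ``lam`` are shared scalars or per-layer
    sequences; ``theta`` may additionally be per-neuron (a sequence of arrays).
    """

    layer_sizes: Sequence[int]
    weights: Sequence[np.ndarray]
    tau: ScalarOrPerLayer
    theta: Union[float, Sequence]
    lam: ScalarOrPerLayer
    approx: ApproxOrders = field(default_factory=ApproxOrders)

    def __post_init__(self):
        sizes = tuple(int(s) for s in self.layer_sizes)
        if len(sizes) < 2 or any(s < 1 for s in sizes):
            raise ValueError("layer_sizes needs an input layer and >= 1 layer of neurons")
        W = [np.asarray(w, dtype=float) for w in self.weights]
        if len(W) != len(sizes) - 1:
            raise ValueError(f"expected {len(sizes) - 1} weight matrices, got {len(W)}")
        for l, w in enumerate(W):
            if w.shape != (sizes[l + 1], sizes[l]):
                raise ValueError(
                    f"layer {l + 1} weights have shape {w.shape}, "
                    f"expected {(sizes[l + 1], sizes[l])}"
                )
        object.__setattr__(self, "layer_sizes", sizes)
        object.__setattr__(self, "weights", tuple(W))

    @property
    def n_layers(self) -> int:
        return len(self.layer_sizes) - 1

    def _per_layer(self, value, name: str) -> list:
        if np.isscalar(value):
            return [value] * self.n_layers
        vals = list(value)
        if len(vals) != self.n_layers:
            raise ValueError(f"{name} must be scalar or one value per layer")
        return vals

    def layer_params(self, l: int) -> tuple:
        """(weight matrix, tau, per-neuron theta array, lam) of layer l (1-based)."""
        if not 1 <= l <= self.n_layers:
            raise ValueError(f"layer index {l} out of range 1..{self.n_layers}")
        taus = self._per_layer(self.tau, "tau")
        lams = self._per_layer(self.lam, "lam")
        thetas = self._per_layer(self.theta, "theta") if not np.isscalar(self.theta) \
            else [self.theta] * self.n_layers
        W = self.weights[l - 1]
        th = np.broadcast_to(np.asarray(thetas[l - 1], dtype=float), (W.shape[0],))
        return W, float(taus[l - 1]), th, float(lams[l - 1])


def layer_sensitivity(
    spec: NetworkSpec, l: int, input_pert: Perturbation, *, boundary: bool = True
) -> LayerSensitivity:
    """Closed-form sensitivity of every neuron in layer ``l`` (1-based)."""
    W, tau, theta, lam = spec.layer_params(l)
    input_pert.require_length(W.shape[1])
    input_pert.require_nonnegative()
    values = np.empty(W.shape[0])
    for i in range(W.shape[0]):
        ctx = ExpectationContext(NeuronParams(W[i], tau, theta[i]), lam, spec.approx)
        try:
            res: SensitivityResult = neuron_sensitivity_closed_form(
                ctx, input_pert, boundary=boundary
            )
        except LifsensError as err:
            raise type(err)(f"layer {l}, neuron {i + 1}: {err}") from err
        values[i] = res.s
    return LayerSensitivity(values)


def snn_sensitivity(
    spec: NetworkSpec, dT1: Perturbation, *, boundary: bool = True
) -> LayerSensitivity:
    """Iterative network sensitivity: each layer's sensitivity vector becomes
    the next layer's input perturbation; returns the output layer's vector."""
    pert = dT1
    out: Optional[LayerSensitivity] = None
    for l in range(1, spec.n_layers + 1):
        out = layer_sensitivity(spec, l, pert, boundary=boundary)
        pert = out.as_perturbation()
    return out


def _forward(times: np.ndarray, spec: NetworkSpec, propagate: str,
             order: Optional[List[np.ndarray]] = None):
    """Propagate a batch of layer-1 input trains through the network.

    Returns (per-output-neuron times (S, n_L), all-fired mask (S,), and the
    per-layer sort permutations used, so a perturbed copy can reuse them —
    the weight-spike association stays fixed at the unperturbed ordering).
    """
    S = times.shape[0]
    fired_all = np.ones(S, dtype=bool)
    perms: List[np.ndarray] = []
    current = times
    for l in range(1, spec.n_layers + 1):
        W, tau, theta, lam = spec.layer_params(l)
        if order is not None:
            perm = order[l - 1]
        else:
            perm = np.argsort(current, axis=1, kind="stable")
        perms.append(perm)
        sorted_times = np.take_along_axis(current, perm, axis=1)
        outputs = np.empty((S, W.shape[0]))
        for i in range(W.shape[0]):
            w_perm = W[i][perm]  # per-sample weight order follows the spike order
            sol = solve_batch(sorted_times, w_perm, tau, theta[i])
            fired_all &= sol.fired
            outputs[:, i] = sol.t_d if propagate == "desired" else sol.t_m
        current = outputs
    return current, fired_all, perms


def network_mc_sensitivity(
    spec: NetworkSpec,
    dT1: Perturbation,
    cfg: MCConfig,
    *,
    propagate: str = "desired",
) -> LayerSensitivity:
    """Monte-Carlo network sensitivity.

    Per sample, a sorted-uniform layer-1 train is propagated through
    unperturbed and perturbed (layer-1 times shifted by ``dT1``) copies of
    the network; the sensitivity of each output neuron is the mean absolute
    difference of its output times over the samples where every neuron on
    both passes fired.  ``propagate`` selects desired (default) or actual
    firing times as the inter-layer spike times.
    """
    if propagate not in ("desired", "actual"):
        raise ValueError("propagate must be 'desired' or 'actual'")
    n0 = spec.layer_sizes[0]
    dT1.require_length(n0)
    _, _, _, lam1 = spec.layer_params(1)
    rng = np.random.default_rng(cfg.seed)
    S = cfg.n_samples
    times = np.sort(rng.uniform(0.0, lam1, (S, n0)), axis=1)

    out0, fired0, perms = _forward(times, spec, propagate)
    out1, fired1, _ = _forward(times + dT1.deltas[None, :], spec, propagate, order=perms)
    valid = fired0 & fired1
    n_excluded = int(S - valid.sum())
    if n_excluded > 0.5 * S:
        raise EstimationUnreliableError(
            f"{n_excluded}/{S} network samples excluded (> 50%)"
        )
    dev = np.abs(out1 - out0)[valid]
    values = dev.mean(axis=0) if valid.any() else np.zeros(spec.layer_sizes[-1])
    if not np.any(dT1.deltas):
        values = np.zeros_like(values)
    return LayerSensitivity(values)
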