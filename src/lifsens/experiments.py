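"""Reproducible parameter sweeps emulating the six reference experiments.

Fixtures follow the experimental conditions of the study this package
reproduces: weights drawn i.i.d. uniform on [0, 1], input spike times sorted
uniforms on [0, lam], and three nested perturbation vectors obtained by
scaling one nonnegative random direction, so that dT1 <= dT2 <= dT3 holds
elementwise and the perturbation-magnitude measure E[du_m] is strictly
increasing across them.

Perturbation magnitudes are specified in E[du_m] units (the canonical
x-axis measure); the scale factor achieving a target measure is found by
scalar root-finding, at the first grid point of a sweep, and then held fixed
across the grid.  The firing threshold defaults to the fraction-of-total-
weight rule theta = 0.4 * sum(w) per neuron, which places the expected
firing index mid-train; it can be overridden per config.

Every sweep is fully determined by its config (all randomness is seeded),
so two runs write byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .errors import ConfigError, LifsensError
from .network import NetworkSpec, network_mc_sensitivity, snn_sensitivity
from .orderstats import (
    ApproxOrders,
    ExpectationContext,
    expected_potential_difference,
    select_j,
    select_m,
)
from .sensitivity import MCConfig, neuron_sensitivity_closed_form, neuron_sensitivity_mc
from .types import NeuronParams, Perturbation

__all__ = [
    "EXPERIMENTS",
    "SweepConfig",
    "generate_weights",
    "generate_network_weights",
    "generate_perturbations",
    "scale_for_measure",
    "default_config",
    "read_config",
    "write_config",
    "run_sweep",
    "write_results",
    "RESULT_COLUMNS",
]

EXPERIMENTS = (
    "perturbation",
    "tau",
    "timesteps",
    "input_dim",
    "network_perturbation",
    "network_input_dim",
)

RESULT_COLUMNS = [
    "experiment",
    "weight_seed",
    "param",
    "param_value",
    "pert_label",
    "pert_scale",
    "E_delta_u_m",
    "j",
    "m",
    "s_closed_form",
    "s_mc",
    "mc_stderr",
    "excluded_fraction",
    "flag",
]


def generate_weights(n: int, seed: int) -> np.ndarray:
    """i.i.d. uniform [0, 1] weights, reproducible by seed.

    Draws of different lengths from the same seed are nested (a longer draw
    extends a shorter one), so input-dimension sweeps use consistent weights.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return np.random.default_rng(seed).uniform(0.0, 1.0, n)


def generate_network_weights(
    layer_sizes: Sequence[int], seed: int, n0_max: Optional[int] = None
) -> List[np.ndarray]:
    """Uniform [0, 1] weight matrices for a fully connected network.

    For input-dimension sweeps, passing ``n0_max`` draws the first-layer
    matrix at that fan-in and slices it to ``layer_sizes[0]`` columns, so
    networks of different input dimension share weights (the sweep isolates
    the dimension effect instead of redrawing everything per grid point).
    """
    rng = np.random.default_rng(seed)
    sizes = list(layer_sizes)
    first_cols = max(n0_max or sizes[0], sizes[0])
    W = [rng.uniform(0.0, 1.0, (sizes[1], first_cols))[:, : sizes[0]]]
    for l in range(1, len(sizes) - 1):
        W.append(rng.uniform(0.0, 1.0, (sizes[l + 1], sizes[l])))
    return W


def generate_perturbations(
    n: int, scales: Sequence[float], seed: int
) -> Tuple[Perturbation, ...]:
    """Nested perturbation vectors: one nonnegative random direction scaled
    by strictly increasing factors."""
    scales = [float(s) for s in scales]
    if any(s < 0 for s in scales):
        raise ValueError("scales must be nonnegative")
    if any(b <= a for a, b in zip(scales, scales[1:])):
        raise ValueError("scales must be strictly increasing")
    base = np.random.default_rng(seed).uniform(0.0, 1.0, n)
    return tuple(Perturbation(s * base) for s in scales)


def perturbation_direction(n: int, seed: int) -> np.ndarray:
    """The unscaled nonnegative direction underlying generate_perturbations."""
    return np.random.default_rng(seed).uniform(0.0, 1.0, n)


def scale_for_measure(
    ctx: ExpectationContext, direction: np.ndarray, target: float
) -> float:
    """Scale factor c such that E[du_m](c * direction) equals ``target``.

    The measure is continuous, zero at zero and strictly increasing in c for
    a nonnegative direction, so a bracketing root-find is exact.
    """
    if target < 0:
        raise ValueError("target measure must be nonnegative")
    if target == 0.0:
        return 0.0
    m = select_m(ctx)

    def f(c: float) -> float:
        return expected_potential_difference(ctx, Perturbation(c * direction), m) - target

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e9:
            raise LifsensError("could not bracket the perturbation scale")
    return float(brentq(f, 0.0, hi, xtol=1e-12, rtol=1e-12))


@dataclass
class SweepConfig:
    """Configuration of one sweep experiment (see :data:`EXPERIMENTS`)."""

    experiment: str
    n: int = 20
    lam: float = 64.0
    tau: float = 50.0
    theta: Optional[float] = None       # explicit threshold; overrides the rule
    theta_fraction: float = 0.4         # theta = fraction * sum(weights) per neuron
    hidden_sizes: Sequence[int] = (5, 1)  # network tail appended to the input size
    grid: Optional[Sequence[float]] = None
    measure_targets: Optional[Sequence[float]] = None  # perturbation experiments
    measure_range: Sequence[float] = (0.0, 0.12)
    n_measure_points: int = 8
    pert_measures: Sequence[float] = (0.04, 0.08, 0.12)  # the three nested dT
    weight_seeds: Sequence[int] = (101, 102, 103)
    pert_seed: int = 7
    mc_samples: int = 10_000
    mc_seed: int = 1
    mc_mode: str = "exact"
    compute_mc: bool = True
    p: Optional[int] = 1
    q: Optional[int] = 3
    output: Optional[str] = None

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ConfigError(
                f"unknown experiment {self.experiment!r}; valid names: "
                + ", ".join(EXPERIMENTS)
            )
        if self.grid is not None and len(self.grid) == 0:
            raise ConfigError("grid must be nonempty")
        # normalize sequence fields so configs compare equal after a YAML
        # round trip
        for name in ("hidden_sizes", "measure_range", "pert_measures",
                     "weight_seeds", "grid", "measure_targets"):
            val = getattr(self, name)
            if val is not None:
                setattr(self, name, tuple(val))

    @property
    def approx(self) -> ApproxOrders:
        return ApproxOrders(self.p, self.q)

    def resolved_grid(self) -> List[float]:
        if self.grid is not None:
            return list(self.grid)
        defaults = {
            "tau": list(range(39, 63)),
            "timesteps": list(range(55, 67)),
            "input_dim": list(range(30, 41)),
            "network_input_dim": list(range(15, 26)),
        }
        if self.experiment in defaults:
            return defaults[self.experiment]
        return []  # perturbation experiments sweep the measure targets instead

    def resolved_targets(self) -> List[float]:
        if self.measure_targets is not None:
            targets = [float(t) for t in self.measure_targets]
        else:
            lo, hi = self.measure_range
            targets = list(np.linspace(hi / self.n_measure_points, hi, self.n_measure_points))
            if lo > 0:
                targets = list(np.linspace(lo, hi, self.n_measure_points))
        if not targets:
            raise ConfigError("no perturbation targets configured")
        return targets


def default_config(experiment: str) -> SweepConfig:
    """The reference parameter settings of each experiment."""
    base = dict(experiment=experiment)
    if experiment == "input_dim":
        base.update(lam=128.0, tau=80.0)
    return SweepConfig(**base)


_CONFIG_FIELDS = {f.name for f in dataclasses.fields(SweepConfig)}


def read_config(path) -> SweepConfig:
    """Load a YAML sweep config, applying experiment defaults for absent keys."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    if "experiment" not in raw:
        raise ConfigError("config is missing the key 'experiment'")
    unknown = set(raw) - _CONFIG_FIELDS
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    cfg = dataclasses.replace(default_config(raw["experiment"]), **raw)
    return cfg


def write_config(cfg: SweepConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_dict(cfg), fh, sort_keys=False)


def config_dict(cfg: SweepConfig) -> dict:
    d = dataclasses.asdict(cfg)
    for key, val in d.items():
        if isinstance(val, tuple):
            d[key] = list(val)
    return d


def _theta_for(cfg: SweepConfig, weights: np.ndarray) -> float:
    return cfg.theta if cfg.theta is not None else cfg.theta_fraction * float(weights.sum())


def _neuron_rows(cfg: SweepConfig) -> List[dict]:
    """Single-neuron experiments: perturbation / tau / timesteps / input_dim."""
    rows: List[dict] = []
    exp = cfg.experiment

    if exp == "perturbation":
        targets = cfg.resolved_targets()
        for ws in cfg.weight_seeds:
            w = generate_weights(cfg.n, ws)
            params = NeuronParams(w, cfg.tau, _theta_for(cfg, w))
            ctx = ExpectationContext(params, cfg.lam, cfg.approx)
            direction = perturbation_direction(cfg.n, cfg.pert_seed)
            for k, target in enumerate(targets):
                rows.append(
                    _one_neuron_point(
                        cfg, ctx, direction, target, weight_seed=ws,
                        param="E_delta_u_m_target", param_value=target,
                        pert_label=f"T{k + 1}",
                    )
                )
        return rows

    # sweeps over tau / lam / n with three nested perturbations
    grid = cfg.resolved_grid()
    if not grid:
        raise ConfigError(f"experiment {exp!r} needs a nonempty grid")
    param = {"tau": "tau", "timesteps": "lam", "input_dim": "n"}[exp]
    ws = cfg.weight_seeds[0]

    def setting(value):
        n = int(value) if param == "n" else cfg.n
        lam = float(value) if param == "lam" else cfg.lam
        tau = float(value) if param == "tau" else cfg.tau
        w = generate_weights(n, ws)
        params = NeuronParams(w, tau, _theta_for(cfg, w))
        return ExpectationContext(params, lam, cfg.approx), n

    # calibrate the three scales at the first grid point, hold them fixed
    ctx0, n0 = setting(grid[0])
    direction0 = perturbation_direction(n0, cfg.pert_seed)
    scales = [scale_for_measure(ctx0, direction0, t) for t in cfg.pert_measures]

    for value in grid:
        ctx, n = setting(value)
        direction = perturbation_direction(n, cfg.pert_seed)
        for k, scale in enumerate(scales):
            rows.append(
                _one_neuron_point(
                    cfg, ctx, direction, None, weight_seed=ws,
                    param=param, param_value=value,
                    pert_label=f"T{k + 1}", scale=scale,
                )
            )
    return rows


def _one_neuron_point(
    cfg: SweepConfig,
    ctx: ExpectationContext,
    direction: np.ndarray,
    target: Optional[float],
    *,
    weight_seed: int,
    param: str,
    param_value: float,
    pert_label: str,
    scale: Optional[float] = None,
) -> dict:
    row = dict.fromkeys(RESULT_COLUMNS, np.nan)
    row.update(
        experiment=cfg.experiment, weight_seed=weight_seed, param=param,
        param_value=param_value, pert_label=pert_label, flag="",
    )
    try:
        if scale is None:
            scale = scale_for_measure(ctx, direction, target)
        pert = Perturbation(scale * direction)
        m = select_m(ctx)
        row["pert_scale"] = scale
        row["E_delta_u_m"] = expected_potential_difference(ctx, pert, m)
        res = neuron_sensitivity_closed_form(ctx, pert)
        row.update(j=res.j, m=res.m, s_closed_form=res.s)
        if cfg.compute_mc:
            mc = neuron_sensitivity_mc(
                ctx, pert, MCConfig(cfg.mc_samples, cfg.mc_seed, cfg.mc_mode)
            )
            row.update(
                s_mc=mc.s, mc_stderr=mc.stderr, excluded_fraction=mc.excluded_fraction
            )
    except LifsensError as err:
        row["flag"] = f"{type(err).__name__}: {err}"
    return row


def _network_rows(cfg: SweepConfig) -> List[dict]:
    rows: List[dict] = []
    exp = cfg.experiment
    mc_cfg = MCConfig(cfg.mc_samples, cfg.mc_seed, "exact")

    n0_max = None
    if exp == "network_input_dim":
        n0_max = int(max(cfg.resolved_grid()))

    def build(n0: int, ws: int) -> NetworkSpec:
        sizes = [n0, *cfg.hidden_sizes]
        W = generate_network_weights(sizes, ws, n0_max)
        thetas = [
            np.array([_theta_for(cfg, W[l][i]) for i in range(W[l].shape[0])])
            for l in range(len(W))
        ]
        return NetworkSpec(sizes, W, cfg.tau, thetas, cfg.lam, cfg.approx)

    def ref_ctx(spec: NetworkSpec) -> ExpectationContext:
        # the perturbation-magnitude measure is anchored at the first
        # input-layer neuron
        W, tau, theta, lam = spec.layer_params(1)
        return ExpectationContext(NeuronParams(W[0], tau, theta[0]), lam, cfg.approx)

    def one_point(spec, direction, scale, *, ws, param, value, label, target=np.nan):
        row = dict.fromkeys(RESULT_COLUMNS, np.nan)
        row.update(
            experiment=exp, weight_seed=ws, param=param, param_value=value,
            pert_label=label, pert_scale=scale, flag="",
        )
        try:
            ctx = ref_ctx(spec)
            pert = Perturbation(scale * direction)
            m = select_m(ctx)
            row["E_delta_u_m"] = expected_potential_difference(ctx, pert, m)
            row["m"], row["j"] = m, select_j(ctx, m) if m > 1 else np.nan
            out = snn_sensitivity(spec, pert)
            row["s_closed_form"] = float(out.values[-1])
            if cfg.compute_mc:
                mc = network_mc_sensitivity(spec, pert, mc_cfg)
                row["s_mc"] = float(mc.values[-1])
                row["excluded_fraction"] = np.nan
        except LifsensError as err:
            row["flag"] = f"{type(err).__name__}: {err}"
        return row

    if exp == "network_perturbation":
        targets = cfg.resolved_targets()
        for ws in cfg.weight_seeds:
            spec = build(cfg.n, ws)
            direction = perturbation_direction(cfg.n, cfg.pert_seed)
            ctx = ref_ctx(spec)
            for k, target in enumerate(targets):
                scale = scale_for_measure(ctx, direction, target)
                rows.append(
                    one_point(spec, direction, scale, ws=ws,
                              param="E_delta_u_m_target", value=target,
                              label=f"T{k + 1}")
                )
        return rows

    # network_input_dim
    grid = [int(v) for v in cfg.resolved_grid()]
    ws = cfg.weight_seeds[0]
    spec0 = build(grid[0], ws)
    direction0 = perturbation_direction(grid[0], cfg.pert_seed)
    scales = [scale_for_measure(ref_ctx(spec0), direction0, t) for t in cfg.pert_measures]
    for n0 in grid:
        spec = build(n0, ws)
        direction = perturbation_direction(n0, cfg.pert_seed)
        for k, scale in enumerate(scales):
            rows.append(
                one_point(spec, direction, scale, ws=ws, param="n0",
                          value=n0, label=f"T{k + 1}")
            )
    return rows


def run_sweep(cfg: SweepConfig) -> pd.DataFrame:
    """Run one experiment sweep; returns a table with one row per
    (grid point x perturbation), optionally writing it to ``cfg.output``."""
    if cfg.experiment in ("network_perturbation", "network_input_dim"):
        rows = _network_rows(cfg)
    else:
        rows = _neuron_rows(cfg)
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if cfg.output:
        write_results(df, cfg.output)
    return df


def write_results(df: pd.DataFrame, path) -> None:
    """CSV with the fixed, documented column order and header."""
    df.to_csv(path, index=False, columns=RESULT_COLUMNS)
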