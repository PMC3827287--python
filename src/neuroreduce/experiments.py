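"""End-to-end experiments: network-vs-reduced validation and robustness.

The central experiment drives a P-population spiking network with smooth,
slowly varying inputs, computes its macroscopic activity a posteriori, and
compares it with the integration of the reduced macroscopic equations that
use the same mean connectivity, synaptic time constant and effective
nonlinearity.  The error metric is, per population, the mean absolute
difference between the two activity traces over the non-transient span,
also reported relative to the network trace's dynamic range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .neuron_models import ModelSpec, build_model, fixed_point, FixedPointError
from .network_sim import NetworkConfig, simulate_network, substream
from .macro_activity import WindowSpec, MacroTrajectory, network_macro
from .effective_nonlinearity import (
    EstimateSettings, NonlinearitySurface, BranchSystem, default_settings,
    build_surface, surface_lookup, deterministic_sweep, _simulate_batch,
    classify_trace, _dispersed_inits,
)
from .reduced_model import ReducedConfig, integrate_regime1, reduced_config_for_model

__all__ = [
    "InputBank",
    "ComparisonResult",
    "generate_inputs",
    "run_comparison",
    "comparison_metrics",
    "compare_model",
    "default_experiment",
    "robustness_sweep",
    "bifurcation_report",
    "pairwise_voltage_correlation",
    "chaos_experiment",
]


# --------------------------------------------------------------------------
# synthetic slow inputs
# --------------------------------------------------------------------------

@dataclass
class InputBank:
    """P smooth per-population input signals built from logistic ramps.

    Each population's base curve is a normalized sum of logistic steps (so
    it is bounded in [-1, 1]); the delivered signal is
    ``offset + gain * base(kappa * t)``.  ``kappa`` compresses time, so a
    larger kappa means faster inputs.
    """

    P: int
    kappa: float
    gain: float
    offset: float
    seed: int
    amplitudes: np.ndarray    # (P, n_ramps)
    centers: np.ndarray       # (P, n_ramps), ms on the base clock
    widths: np.ndarray        # (P, n_ramps), ms on the base clock

    def base(self, a: int, t):
        t = np.asarray(t, dtype=float)
        acc = np.zeros_like(t)
        for A, c, w in zip(self.amplitudes[a], self.centers[a], self.widths[a]):
            acc = acc + A / (1.0 + np.exp(-(t - c) / w))
        return acc

    def __call__(self, t: float) -> np.ndarray:
        tt = self.kappa * t
        return np.array([self.offset + self.gain * self.base(a, tt)
                         for a in range(self.P)], dtype=float)

    def value_range(self, T: float, n: int = 512) -> np.ndarray:
        ts = np.linspace(0.0, T, n)
        vals = np.array([self(t) for t in ts])
        return np.array([vals.min(), vals.max()])


def generate_inputs(P: int, kappa: float = 1.0, gain: float = 1.0,
                    offset: float = 0.0, seed: int = 0,
                    T_base: float = 2000.0, n_ramps: int = 4) -> InputBank:
    """Reproducible smooth per-population inputs (slow at kappa = 1).

    Ramp widths are drawn between T_base/40 and T_base/15, so at kappa = 1
    the signals vary over hundreds of milliseconds -- slow relative to all
    neuronal timescales of the supported models.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    rng = substream(seed, "inputs")
    A = rng.uniform(-1.0, 1.0, size=(P, n_ramps))
    A /= np.abs(A).sum(axis=1, keepdims=True)   # base curve bounded in [-1, 1]
    centers = rng.uniform(0.12 * T_base, 0.88 * T_base, size=(P, n_ramps))
    widths = rng.uniform(T_base / 40.0, T_base / 15.0, size=(P, n_ramps))
    return InputBank(P=P, kappa=kappa, gain=gain, offset=offset, seed=seed,
                     amplitudes=A, centers=centers, widths=widths)


# --------------------------------------------------------------------------
# comparison
# --------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    network: MacroTrajectory
    reduced: MacroTrajectory
    mad: np.ndarray               # (P,) mean absolute difference, mV
    dynamic_range: np.ndarray     # (P,) network-trace range over valid span
    relative_error: np.ndarray    # (P,) mad / dynamic_range
    seed: int = 0
    config: Dict = field(default_factory=dict)


def comparison_metrics(net: MacroTrajectory, red: MacroTrajectory
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-population MAD / range / relative error on the non-transient span.

    The reduced trace is linearly interpolated onto the network time grid;
    samples flagged transient in either trace are excluded from both.
    """
    if net.P != red.P:
        raise ValueError("population count mismatch")
    t = net.time
    red_on_net = np.vstack([np.interp(t, red.time, red.nu[a]) for a in range(red.P)])
    valid = ~net.transient_mask
    red_mask = np.interp(t, red.time, red.transient_mask.astype(float)) > 0
    valid &= ~red_mask
    valid &= (t >= red.time[0]) & (t <= red.time[-1])
    if valid.sum() < 2:
        raise ValueError("no overlapping non-transient samples")
    diff = np.abs(net.nu[:, valid] - red_on_net[:, valid])
    mad = diff.mean(axis=1)
    rng = np.ptp(net.nu[:, valid], axis=1)
    rel = mad / np.maximum(rng, 1e-12)
    return mad, rng, rel


def run_comparison(spec: ModelSpec, net_config: NetworkConfig,
                   red_config: ReducedConfig, window: WindowSpec,
                   seed: Optional[int] = None) -> ComparisonResult:
    """Simulate the network, window it, integrate the reduced model, compare."""
    if net_config.P != red_config.P:
        raise ValueError("configs must share P")
    if not np.allclose(net_config.J_mean, red_config.J_mean):
        raise ValueError("configs must share the mean connectivity")
    if not np.isclose(net_config.tau_s, red_config.tau_s):
        raise ValueError("configs must share tau_s")
    if seed is not None:
        net_config = dc_replace(net_config, seed=seed)
    traj = simulate_network(net_config)
    net_macro = network_macro(traj, window)
    red_macro = integrate_regime1(red_config)
    mad, rng, rel = comparison_metrics(net_macro, red_macro)
    return ComparisonResult(network=net_macro, reduced=red_macro, mad=mad,
                            dynamic_range=rng, relative_error=rel,
                            seed=net_config.seed,
                            config={"P": net_config.P, "N": net_config.N,
                                    "tau_s": net_config.tau_s,
                                    "sigma": spec.noise_V,
                                    "dt": net_config.dt})


# --------------------------------------------------------------------------
# packaged default experiments (per model)
# --------------------------------------------------------------------------

_MODEL_EXPERIMENT_DEFAULTS: Dict[str, Dict] = {
    # input gain/offset chosen so the effective input sweeps across the
    # model's oscillation onset; coupling moderate; noise moderate
    "mckean": dict(sigma=0.2, gain=3.0, offset=0.0, j_scale=0.5,
                   j_disorder=0.3, tau_s=15.0, window=60.0, dt_net=0.05,
                   dt_red=0.05, T_total=2000.0, surface_I=(-14.0, 14.0, 57),
                   n_inits=4),
    "fhn": dict(sigma=0.15, gain=1.3, offset=0.5, j_scale=0.30,
                j_disorder=0.05, tau_s=15.0, window=60.0, dt_net=0.05,
                dt_red=0.05, T_total=2000.0, surface_I=(-5.0, 7.0, 49),
                n_inits=4),
    # Hodgkin-Huxley: high noise (regime I) and weak coupling, where the
    # single-branch reduction is applicable
    "hh": dict(sigma=3.0, gain=5.0, offset=4.0, j_scale=0.05,
               j_disorder=0.02, tau_s=15.0, window=20.0, dt_net=0.01,
               dt_red=0.05, T_total=800.0, surface_I=(-12.0, 22.0, 35),
               n_inits=4),
}


def default_experiment(model_id: str, seed: int = 0, P: int = 3, N: int = 200,
                       structure_seed: int = 1234, kappa: float = 1.0,
                       input_heterogeneity: float = 0.0,
                       surface: Optional[NonlinearitySurface] = None,
                       model_params: Optional[Dict] = None,
                       **overrides) -> Dict:
    """Assemble the full configuration set for a comparison experiment.

    Returns a dict with spec, inputs, weights statistics, the nonlinearity
    surface (built here at the experiment's noise level unless supplied),
    the network and reduced configs and the averaging window.  The mean
    connectivity matrix is drawn once from a normal law with scale
    ``j_scale`` using ``structure_seed`` (held fixed across noise seeds).
    """
    d = dict(_MODEL_EXPERIMENT_DEFAULTS[model_id])
    d.update(overrides)
    spec = build_model(model_id, noise_V=d["sigma"], **(model_params or {}))
    T_total = d["T_total"] / kappa

    inputs = generate_inputs(P, kappa=kappa, gain=d["gain"], offset=d["offset"],
                             seed=structure_seed, T_base=d["T_total"])
    rng_struct = substream(structure_seed, "jmean")
    J_mean = rng_struct.normal(0.0, d["j_scale"], size=(P, P))
    J_dis = np.full((P, P), d["j_disorder"])

    if surface is None:
        lo, hi, npts = d["surface_I"]
        settings = default_settings(spec)
        surface = build_surface(spec, np.linspace(lo, hi, int(npts)),
                                [d["sigma"]], n_inits=d["n_inits"],
                                settings=settings, seed=structure_seed)
    sigma = d["sigma"]

    def S_lookup(I, _s=surface, _sig=sigma):
        return surface_lookup(_s, I, _sig, branch="pooled")

    net_config = NetworkConfig(
        spec=spec, P=P, N=(N,) * P, J_mean=J_mean, J_disorder=J_dis,
        tau_s=d["tau_s"], inputs=inputs,
        input_heterogeneity=input_heterogeneity,
        dt=d["dt_net"], T_total=T_total, seed=seed,
        record_stride=max(1, int(round(1.0 / d["dt_net"]))), store_aux=False)

    red_config = reduced_config_for_model(
        spec, P=P, J_mean=J_mean, tau_s=d["tau_s"], nonlinearities=S_lookup,
        inputs=inputs, dt=d["dt_red"], T_total=T_total)

    window = WindowSpec(width=d["window"], dt=net_config.dt * net_config.record_stride)
    return dict(spec=spec, inputs=inputs, J_mean=J_mean, surface=surface,
                net_config=net_config, red_config=red_config, window=window,
                params=d)


def compare_model(model_id: str, seed: int = 0, **kwargs) -> ComparisonResult:
    """Default network-vs-reduced comparison for one model and seed."""
    exp = default_experiment(model_id, seed=seed, **kwargs)
    res = run_comparison(exp["spec"], exp["net_config"], exp["red_config"],
                         exp["window"])
    res.config.update({"model": model_id, **{k: v for k, v in exp["params"].items()
                                             if np.isscalar(v)}})
    return res


# --------------------------------------------------------------------------
# robustness sweeps
# --------------------------------------------------------------------------

_SWEEPABLE = {"lambda", "J", "N", "sigma_J", "sigma", "kappa", "tau_s"}


def robustness_sweep(parameter: str, values: Sequence, model_id: str = "mckean",
                     seeds: Sequence[int] = (0, 1), **base) -> pd.DataFrame:
    """Run the comparison experiment across one parameter's values.

    Emits a tidy table (parameter, value, seed, population, mad,
    relative_error); individual run failures are recorded per row and the
    sweep continues.
    """
    if parameter not in _SWEEPABLE:
        raise ValueError(f"unknown parameter {parameter!r}; known: {sorted(_SWEEPABLE)}")
    rows = []
    surface_cache: Dict[float, NonlinearitySurface] = {}
    for value in values:
        kw = dict(base)
        if parameter == "lambda":
            kw["input_heterogeneity"] = float(value)
        elif parameter == "J":
            kw["j_scale"] = float(value)
        elif parameter == "N":
            kw["N"] = int(value)
        elif parameter == "sigma_J":
            kw["j_disorder"] = float(value)
        elif parameter == "sigma":
            kw["sigma"] = float(value)
        elif parameter == "kappa":
            kw["kappa"] = float(value)
        elif parameter == "tau_s":
            kw["tau_s"] = float(value)
        sigma_key = float(kw.get("sigma",
                                 _MODEL_EXPERIMENT_DEFAULTS[model_id]["sigma"]))
        for seed in seeds:
            try:
                if sigma_key not in surface_cache:
                    exp = default_experiment(model_id, seed=int(seed), **kw)
                    surface_cache[sigma_key] = exp["surface"]
                res = compare_model(model_id, seed=int(seed),
                                    surface=surface_cache[sigma_key], **kw)
                for a in range(len(res.mad)):
                    rows.append(dict(parameter=parameter, value=value,
                                     seed=int(seed), population=a,
                                     mad=float(res.mad[a]),
                                     relative_error=float(res.relative_error[a]),
                                     error=None))
            except Exception as e:  # noqa: BLE001 - recorded, sweep continues
                rows.append(dict(parameter=parameter, value=value,
                                 seed=int(seed), population=-1,
                                 mad=np.nan, relative_error=np.nan,
                                 error=str(e)))
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# bifurcation report
# --------------------------------------------------------------------------

def _onset_periods(spec: ModelSpec, bs: BranchSystem,
                   settings: EstimateSettings, deltas=(1e-3, 1e-1)):
    """Cycle periods just above the (refined) cycle fold.

    Starts from a state on the cycle at the grid-level fold and continues
    it downward: first bisect the true fold between the last grid input
    with a cycle and the grid input below it, then measure the period at
    fold + delta * span for each requested relative delta.
    """
    if bs.I_cycle.size == 0:
        return None, {}
    I_on_grid = float(bs.I_cycle[0])
    grid_all = np.unique([p.I for p in bs.points])
    lower = grid_all[grid_all < I_on_grid]
    I_below = float(lower[-1]) if lower.size else I_on_grid
    span = float(grid_all[-1] - grid_all[0])

    # land on the cycle at the grid fold
    state = _dispersed_inits(spec, 2, substream(7, "onset"))[0][None, :]
    for I_step in (float(bs.I_cycle[-1]), I_on_grid):
        mean, _, traces, trace_dt, _, state = _simulate_batch(
            spec, np.array([I_step]), 0.0, state, settings, None)
    period, _, settled = classify_trace(traces[0], trace_dt, float(mean[0]))
    if period is None:
        return I_on_grid, {}

    lo, hi = I_below, I_on_grid
    st_hi = state.copy()
    for _ in range(6):
        mid = 0.5 * (lo + hi)
        mean, _, traces, trace_dt, _, st_mid = _simulate_batch(
            spec, np.array([mid]), 0.0, st_hi.copy(), settings, None)
        p_mid, _, _ = classify_trace(traces[0], trace_dt, float(mean[0]))
        if p_mid is None:
            lo = mid
        else:
            hi = mid
            st_hi = st_mid
    fold = hi

    periods = {}
    for dl in deltas:
        I_test = fold + dl * span
        mean, _, traces, trace_dt, _, _ = _simulate_batch(
            spec, np.array([I_test]), 0.0, st_hi.copy(), settings, None)
        p, _, _ = classify_trace(traces[0], trace_dt, float(mean[0]))
        if p is not None:
            periods[dl] = p
    return fold, periods


def bifurcation_report(spec: ModelSpec, I_grid: Sequence[float],
                       settings: Optional[EstimateSettings] = None,
                       classify: bool = True,
                       branch_system: Optional[BranchSystem] = None):
    """Bifurcation table plus an excitability-class heuristic.

    Wraps ``deterministic_sweep``.  The class heuristic compares the cycle
    period very close to onset with the period a tenth of the grid span
    above it: a substantial growth (>= 30%) marks arbitrarily slow orbits
    near onset (class I); a flat period marks oscillations appearing at
    finite frequency (class II).
    """
    if settings is None:
        settings = default_settings(spec)
    bs = branch_system if branch_system is not None else deterministic_sweep(
        spec, I_grid, settings)
    rows = []
    for p in bs.points:
        rows.append(dict(I=p.I, direction=p.direction, value=p.value,
                         mean_voltage=p.mean_voltage, period=p.period,
                         frequency=(1000.0 / p.period if p.period else np.nan),
                         settled=p.settled))
    table = pd.DataFrame(rows)
    window = bs.bistable_window
    info = dict(bistable=window is not None,
                bistable_window=window,
                onset_frequency=bs.onset_frequency(),
                excitability_class=None,
                branch_system=bs)
    if classify and bs.I_cycle.size:
        fold, periods = _onset_periods(spec, bs, settings)
        info["refined_fold"] = fold
        info["onset_periods"] = periods
        if len(periods) == 2:
            dl_small, dl_big = sorted(periods)
            growth = periods[dl_small] / periods[dl_big]
            info["excitability_class"] = "I" if growth >= 1.3 else "II"
    return table, info


# --------------------------------------------------------------------------
# propagation-of-chaos diagnostic
# --------------------------------------------------------------------------

def chaos_experiment(N: int, seed: int, sigma: float = 0.2, J: float = 1.7,
                     I: float = 0.0, J_disorder: float = 0.5,
                     T_total: float = 2500.0, t_min: float = 500.0) -> float:
    """Mean within-population pairwise correlation at population size N.

    One self-coupled population of noisy McKean oscillators under constant
    input, operated near the mean-field synchronization threshold.  At small
    N the finite-size fluctuation of the mean field pushes individual
    realizations over the entrainment threshold (large pairwise
    correlation); as N grows the fluctuations — and with them the
    correlation — vanish, the empirical signature of propagation of chaos.
    Realizations are bimodal at small N, so the diagnostic is the mean over
    several seeds.
    """
    spec = build_model("mckean", noise_V=sigma)
    cfg = NetworkConfig(spec=spec, P=1, N=(int(N),), J_mean=[[J]],
                        J_disorder=[[J_disorder]], tau_s=15.0, inputs=I,
                        dt=0.05, T_total=T_total, seed=seed, store_aux=False)
    traj = simulate_network(cfg)
    return pairwise_voltage_correlation(traj, 0, t_min=t_min)


def pairwise_voltage_correlation(traj, population: int = 0,
                                 t_min: float = 0.0) -> float:
    """Mean pairwise within-population voltage correlation over a window.

    Computed on the stationary part of the trajectory (t >= t_min) as the
    exact average over all N(N-1)/2 distinct pairs, via the identity
    r_bar = (N * Var(mean of standardized traces) - 1) / (N - 1), which is
    far less noisy than sampling pairs.
    """
    idx = np.nonzero(traj.population_index == population)[0]
    keep = traj.time >= t_min
    V = traj.V[np.ix_(idx, keep)].astype(np.float64)
    V = V - V.mean(axis=1, keepdims=True)
    sd = V.std(axis=1)
    ok = sd > 1e-12
    Z = V[ok] / sd[ok][:, None]
    N = Z.shape[0]
    if N < 2:
        raise ValueError("need at least two fluctuating neurons")
    var_mean = float(Z.mean(axis=0).var())
    return (N * var_mean - 1.0) / (N - 1.0)
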