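"""Effective nonlinearity S of a neuron model.

The macroscopic reduction closes the population equation with one unknown
function: the map S(I, sigma) from a constant effective input (and noise
level) to the long-run temporal average of the residual observable ``r``
(voltage drift minus linear part and input) of a single uncoupled neuron.

Three routes to S are provided:

* ``mckean_sigmoid`` -- closed form for the deterministic McKean neuron.
  With the N-shaped piecewise-linear nullcline the slow flow on each outer
  branch is linear, so the transit times T-/T+ along the two slow manifolds
  are logarithms, and the cycle-averaged observable is their weighted
  combination.  The result is a non-smooth sigmoid with vertical tangents
  at the oscillation thresholds.

* ``estimate_point`` / ``build_surface`` -- numerical estimation for any
  model and noise level: simulate one noisy neuron at constant input from
  several dispersed initial conditions, discard the transient, average the
  observable, and segment the per-initial-condition values into one or two
  branches (regime I / regime II).

* ``deterministic_sweep`` -- noise-free bifurcation diagram via forward and
  backward hysteresis sweeps over the input grid, continuing the attractor
  state from point to point; disagreement between the sweeps delimits the
  bistable window and yields the fixed-point and cycle branch systems used
  by the regime II macroscopic integrator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .neuron_models import (
    ModelSpec, McKeanParams, drift, observable, noise_amplitudes,
    fixed_point, FixedPointError, hh_gating_steady_state,
)
from .network_sim import substream

__all__ = [
    "OutsideOscillatoryWindow",
    "TooManyBranchesError",
    "HullError",
    "EstimateSettings",
    "PointEstimate",
    "NonlinearitySurface",
    "BranchSystem",
    "mckean_oscillatory_window",
    "mckean_transit_times",
    "mckean_sigmoid",
    "mckean_branch_levels",
    "default_settings",
    "estimate_point",
    "build_surface",
    "deterministic_sweep",
    "surface_lookup",
    "split_branches",
    "measure_period",
    "surface_to_json",
    "surface_from_json",
    "surface_to_csv",
]


class OutsideOscillatoryWindow(ValueError):
    """Input outside the interval where the deterministic cycle exists."""


class TooManyBranchesError(RuntimeError):
    """More than two well-separated attractor branches detected."""


class HullError(ValueError):
    """Query outside the tabulated (I, sigma) hull."""


# --------------------------------------------------------------------------
# analytic path: deterministic McKean neuron
# --------------------------------------------------------------------------

def mckean_oscillatory_window(params: McKeanParams) -> Tuple[float, float]:
    """Input interval (I_lo, I_hi) on which the deterministic cycle exists.

    Outside, the system has a single stable fixed point on the negative
    (below) or positive (above) slow manifold.
    """
    m, b, eps = params.slope_mid, params.b, params.eps
    if 1.0 / b <= m:
        raise ValueError("no oscillatory window: need slope_mid < 1/b")
    I_lo = params.v_lo * (1.0 / b - m) / eps
    I_hi = params.v_hi * (1.0 / b - m) / eps
    return I_lo, I_hi


def _mckean_geometry(params: McKeanParams, I):
    m = params.slope_mid
    s = -params.slope_outer
    b = params.b
    eI = params.eps * np.asarray(I, dtype=float)
    w_top = m * params.v_hi + eI      # right knee of the nullcline
    w_bot = m * params.v_lo + eI      # left knee
    A_plus = ((s + m) * params.v_hi + eI) / (1.0 + b * s)
    A_minus = ((s + m) * params.v_lo + eI) / (1.0 + b * s)
    rate = params.c * (b + 1.0 / s)
    return w_top, w_bot, A_plus, A_minus, rate


def mckean_transit_times(I: float, params: McKeanParams) -> Tuple[float, float]:
    """Closed-form transit times (T_minus, T_plus) along the slow manifolds.

    On each outer branch of the piecewise-linear nullcline the adaptation
    variable follows a linear ODE, so the time to traverse the branch
    between the two knee levels is a logarithm.  Only defined inside the
    oscillatory window.
    """
    I_lo, I_hi = mckean_oscillatory_window(params)
    if not (I_lo < I < I_hi):
        raise OutsideOscillatoryWindow(
            f"I={I} outside oscillatory window ({I_lo:.6g}, {I_hi:.6g})")
    w_top, w_bot, A_plus, A_minus, rate = _mckean_geometry(params, I)
    T_plus = np.log((A_plus - w_bot) / (A_plus - w_top)) / rate
    T_minus = np.log((w_top - A_minus) / (w_bot - A_minus)) / rate
    return float(T_minus), float(T_plus)


def mckean_branch_levels(params: McKeanParams) -> Tuple[float, float]:
    """Observable value on the negative / positive slow manifold.

    The residual observable r = (f(v) + s v)/eps is constant on each outer
    branch of the nullcline.
    """
    m = params.slope_mid
    s = -params.slope_outer
    r_minus = (m + s) * params.v_lo / params.eps
    r_plus = (m + s) * params.v_hi / params.eps
    return r_minus, r_plus


def mckean_sigmoid(I, params: McKeanParams):
    """Effective nonlinearity of the deterministic McKean neuron.

    Piecewise: outside the oscillatory window the observable sits at its
    constant value on the stable fixed-point branch; inside, it is the
    transit-time-weighted average of the two slow-branch levels.  The
    function is continuous and non-decreasing, with vertical tangents at
    the two thresholds (the transit time on the branch hosting the
    disappearing fixed point diverges logarithmically).
    """
    I = np.asarray(I, dtype=float)
    scalar = I.ndim == 0
    I = np.atleast_1d(I)
    I_lo, I_hi = mckean_oscillatory_window(params)
    r_minus, r_plus = mckean_branch_levels(params)
    out = np.empty_like(I)
    out[I <= I_lo] = r_minus
    out[I >= I_hi] = r_plus
    inside = (I > I_lo) & (I < I_hi)
    if inside.any():
        w_top, w_bot, A_plus, A_minus, rate = _mckean_geometry(params, I[inside])
        T_plus = np.log((A_plus - w_bot) / (A_plus - w_top)) / rate
        T_minus = np.log((w_top - A_minus) / (w_bot - A_minus)) / rate
        out[inside] = (T_minus * r_minus + T_plus * r_plus) / (T_minus + T_plus)
    return float(out[0]) if scalar else out


# --------------------------------------------------------------------------
# numerical path
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EstimateSettings:
    """Horizons and resolution for temporal-average estimation.

    Defaults (per model, see ``default_settings``): transient at least ten
    times the slowest intrinsic timescale, averaging at least twenty
    detected periods.
    """

    dt: float = 0.02
    t_transient: float = 500.0
    t_average: float = 1000.0
    n_batches: int = 16
    trace_samples: int = 4096
    autocorr_threshold: float = 0.2
    separation_fraction: float = 0.02   # min branch gap as fraction of surface span
    gap_factor: float = 5.0


def default_settings(spec: ModelSpec, **overrides) -> EstimateSettings:
    base = {
        "mckean": dict(dt=0.02, t_transient=600.0, t_average=1500.0),
        "fhn": dict(dt=0.02, t_transient=300.0, t_average=900.0),
        "hh": dict(dt=0.01, t_transient=150.0, t_average=600.0),
    }.get(spec.model_id, {})
    base.update(overrides)
    return EstimateSettings(**base)


@dataclass
class PointEstimate:
    value: float
    stderr: float
    period: Optional[float] = None      # ms, None if stationary
    mean_voltage: float = float("nan")
    warning: Optional[str] = None


def measure_period(trace: np.ndarray, dt: float, threshold: float = 0.2
                   ) -> Optional[float]:
    """Dominant period of a settled trace via its autocorrelation.

    Returns None when no autocorrelation peak exceeds ``threshold``
    (stationary regime).  The estimate is refined by locating the farthest
    clean multiple of the first peak and dividing, plus parabolic
    sub-sample interpolation.
    """
    x = np.asarray(trace, dtype=float)
    n = len(x)
    if n < 16:
        return None
    x = x - x.mean()
    e0 = float(np.dot(x, x))
    if e0 < 1e-20:
        return None
    ac_raw = np.correlate(x, x, mode="full")[n - 1:]
    m = n // 2
    ac = ac_raw[:m] / e0            # biased: decays with lag, robust peaks
    below = np.nonzero(ac < 0)[0]
    if below.size == 0 or below[0] >= m - 2:
        return None
    start = below[0]
    k1 = start + int(np.argmax(ac[start:]))
    # biased estimate shrinks peaks by (1 - lag/n); undo for the threshold
    if k1 <= 1 or ac[k1] / max(1e-12, 1.0 - k1 / n) < threshold:
        return None
    # guard against locking on a multiple of the true period: if a peak of
    # comparable height exists near half the lag, descend to it
    for _ in range(3):
        half = k1 // 2
        if half <= max(1, start):
            break
        lo = max(1, half - max(2, k1 // 8))
        hi = min(m, half + max(2, k1 // 8) + 1)
        kh = lo + int(np.argmax(ac[lo:hi]))
        if kh in (lo, hi - 1) or ac[kh] < 0.85 * ac[k1]:
            break
        k1 = kh
    # refine: hill-climb from multiples of k1 as far out as the peaks stay
    # clean, then divide the far-peak lag by the cycle count
    best_k, best_K = k1, 1
    K = 2
    while K * k1 < m - 2:
        c0 = K * k1 if best_K == 1 else int(round(best_k * K / best_K))
        lo = max(start, c0 - max(2, k1 // 3))
        hi = min(m, c0 + max(2, k1 // 3) + 1)
        if hi - lo < 3:
            break
        kK = lo + int(np.argmax(ac[lo:hi]))
        if ac[kK] / max(1e-12, 1.0 - kK / n) < 0.5 * threshold or kK in (lo, hi - 1):
            break
        best_k, best_K = kK, K
        K += 1
    delta = 0.0
    if 1 <= best_k < m - 1:
        y0, y1, y2 = ac[best_k - 1], ac[best_k], ac[best_k + 1]
        denom = y0 - 2.0 * y1 + y2
        if abs(denom) > 1e-15:
            delta = float(np.clip(0.5 * (y0 - y2) / denom, -1.0, 1.0))
    return (best_k + delta) * dt / best_K


def _simulate_batch(spec: ModelSpec, I: np.ndarray, sigma: float,
                    inits: np.ndarray, settings: EstimateSettings,
                    rng: Optional[np.random.Generator]):
    """Euler-Maruyama for a batch of independent neurons at constant inputs.

    Returns per-neuron observable mean, batch-means standard error,
    observable traces over the averaging horizon (subsampled), the trace
    step, the mean voltage, and the final states.  The three built-in
    models run through compiled kernels; registered custom models fall back
    to a generic vectorized loop.
    """
    spec_n = replace(spec, noise_V=float(sigma))
    g = noise_amplitudes(spec_n)
    dt = settings.dt
    B = len(I)
    X = np.array(inits, dtype=float).reshape(B, spec.state_dim)
    I = np.asarray(I, dtype=float)

    n_tr = int(round(settings.t_transient / dt))
    n_av = int(round(settings.t_average / dt))
    stride = max(1, n_av // settings.trace_samples)
    n_trace = max(1, n_av // stride)
    nb = max(2, settings.n_batches)
    batch_len = max(1, n_av // nb)

    if spec.model_id in ("mckean", "fhn", "hh"):
        from . import _kernels
        seed = int(rng.integers(2 ** 31)) if rng is not None else 0
        common = (X, I, dt, n_tr, n_av, g, seed, stride, nb, n_trace)
        p = spec.params
        if spec.model_id == "mckean":
            out = _kernels.mckean_run(*common, p.v_lo, p.v_hi, p.slope_mid,
                                      p.slope_outer, p.b, p.c, p.eps)
        elif spec.model_id == "fhn":
            out = _kernels.fhn_run(*common, p.c1, p.c3, p.a, p.b, p.tau_w,
                                   p.reduction_slope)
        else:
            out = _kernels.hh_run(*common, p.C, p.gNa, p.gK, p.gL,
                                  p.ENa, p.EK, p.EL)
        r_sum, v_sum, batch_sums, traces, ti, blow = out
        if blow >= 0:
            raise FloatingPointError(
                f"blow-up at t={blow * dt:.6g} ms; consider a smaller dt")
    else:
        noisy = np.nonzero(g > 0)[0]
        sqdt = np.sqrt(dt)

        def step():
            X[...] = X + dt * drift(spec, X, I)
            for j in noisy:
                X[:, j] += sqdt * g[j] * rng.standard_normal(B)

        for k in range(n_tr):
            step()
            if (k + 1) % 500 == 0 and not np.all(np.isfinite(X[:, 0])):
                raise FloatingPointError(
                    f"blow-up during transient at t={(k + 1) * dt:.3g} ms")
        r_sum = np.zeros(B)
        v_sum = np.zeros(B)
        batch_sums = np.zeros((nb, B))
        traces = np.empty((B, n_trace))
        ti = 0
        for k in range(n_av):
            r = observable(spec, X)
            r_sum += r
            v_sum += X[:, spec.voltage_index]
            bi = min(k // batch_len, nb - 1)
            batch_sums[bi] += r
            if k % stride == 0 and ti < n_trace:
                traces[:, ti] = r
                ti += 1
            step()
        if not np.all(np.isfinite(X)):
            raise FloatingPointError("blow-up during averaging horizon")

    mean = r_sum / n_av
    lens = np.full(nb, batch_len, dtype=float)
    lens[-1] = n_av - batch_len * (nb - 1)
    bmeans = batch_sums / lens[:, None]
    se = bmeans.std(axis=0, ddof=1) / np.sqrt(nb)
    return mean, se, traces[:, :ti], stride * dt, v_sum / n_av, X


def classify_trace(trace: np.ndarray, dt: float, mean: float,
                   threshold: float = 0.2):
    """(period, stationary, settled) classification of a settled trace.

    A trace whose second half stays within a small band is stationary (the
    autocorrelation of residual damped ringing is ignored); otherwise a
    period is sought; a trace with neither is unsettled.
    """
    half = trace[len(trace) // 2:]
    if np.ptp(half) < max(1e-3, 1e-3 * abs(mean)):
        return None, True, True
    period = measure_period(trace, dt, threshold)
    if period is None:
        return None, False, False
    return period, False, True


def estimate_point(spec: ModelSpec, I: float, sigma: float,
                   init: Optional[Sequence[float]] = None,
                   settings: Optional[EstimateSettings] = None,
                   rng: Optional[np.random.Generator] = None,
                   seed: int = 0) -> PointEstimate:
    """Temporal average of the observable for one neuron at constant input.

    Simulates a single uncoupled neuron, discards the initial transient and
    returns the time average of the residual observable together with a
    batch-means standard error.  A warning is recorded when the averaging
    horizon is shorter than twenty detected oscillation periods.
    """
    if settings is None:
        settings = default_settings(spec)
    if rng is None:
        rng = substream(seed, "estimate")
    if init is None:
        init = _dispersed_inits(spec, 1, substream(seed, "inits"))[0]
    mean, se, traces, trace_dt, vbar, _ = _simulate_batch(
        spec, np.array([I], dtype=float), sigma,
        np.array(init, dtype=float)[None, :], settings, rng)
    period = measure_period(traces[0], trace_dt, settings.autocorr_threshold)
    warning = None
    if period is not None and settings.t_average < 20.0 * period:
        warning = (f"averaging horizon {settings.t_average} ms < 20 periods "
                   f"({period:.3g} ms each)")
    return PointEstimate(value=float(mean[0]), stderr=float(se[0]),
                         period=period, mean_voltage=float(vbar[0]),
                         warning=warning)


def _dispersed_inits(spec: ModelSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Initial conditions spread over the model's physiological state box."""
    if spec.model_id == "hh":
        V = rng.uniform(-10.0, 105.0, size=n)
        gates = hh_gating_steady_state(spec.params, V)
        gates = np.clip(gates + rng.uniform(-0.1, 0.1, size=gates.shape), 0.0, 1.0)
        return np.column_stack([V, gates])
    if spec.model_id == "mckean":
        lo, hi = 2.5 * spec.params.v_lo, 2.5 * spec.params.v_hi
        v = rng.uniform(lo, hi, size=n)
        w = rng.uniform(lo * spec.params.slope_mid, hi * spec.params.slope_mid, size=n)
        return np.column_stack([v, w])
    if spec.model_id == "fhn":
        v = rng.uniform(-2.5, 2.5, size=n)
        w = rng.uniform(-1.0, 2.5, size=n)
        return np.column_stack([v, w])
    return rng.standard_normal((n, spec.state_dim))


def _excited_state(spec: ModelSpec) -> np.ndarray:
    """A strongly depolarized state, in the spiking attractor's basin."""
    if spec.model_id == "hh":
        V = 100.0
        return np.concatenate([[V], hh_gating_steady_state(spec.params, V)])
    if spec.model_id == "mckean":
        return np.array([2.0 * spec.params.v_hi,
                         spec.params.slope_mid * spec.params.v_lo])
    if spec.model_id == "fhn":
        return np.array([2.0, -0.5])
    return np.ones(spec.state_dim)


def _anchored_inits(spec: ModelSpec, I: float, n: int,
                    dispersed: np.ndarray) -> np.ndarray:
    """Initial conditions for one input level: the deterministic fixed point
    (when it exists), an excited state, and dispersed fillers.

    Anchoring guarantees both basins are sampled wherever a fixed point and
    a cycle coexist, which a small number of random states can miss.  The
    equilibrium anchor is slightly jittered: root-finding may return an
    *unstable* equilibrium, on which a deterministic trajectory would
    otherwise sit forever and fabricate a spurious branch; the jitter lets
    it escape during the discarded transient while staying inside the basin
    of a genuinely stable fixed point.
    """
    rows = []
    try:
        fp = fixed_point(spec, I)
        jit = 1e-2 * np.ones_like(fp)
        rows.append(fp + jit)
    except FixedPointError:
        pass
    rows.append(_excited_state(spec))
    need = n - len(rows)
    if need > 0:
        rows.extend(dispersed[:need])
    return np.array(rows[:n])


# --------------------------------------------------------------------------
# branch clustering
# --------------------------------------------------------------------------

def split_branches(values: Sequence[float], stderrs: Sequence[float],
                   min_separation: float, gap_factor: float = 5.0
                   ) -> List[np.ndarray]:
    """Segment 1-D point estimates into 1 or 2 clusters by the largest gap.

    Two clusters are declared iff the largest sorted gap exceeds
    max(gap_factor * median of the other gaps, gap_factor * pooled standard
    error, min_separation).  More than two well-separated clusters raise
    ``TooManyBranchesError``.

    Returns a list of index arrays (ascending cluster means).
    """
    values = np.asarray(values, dtype=float)
    stderrs = np.asarray(stderrs, dtype=float)
    order = np.argsort(values)
    n = len(values)
    if n < 2:
        return [order]
    sv = values[order]
    gaps = np.diff(sv)
    pooled_se = float(np.sqrt(np.mean(stderrs ** 2)))

    def threshold(other_gaps):
        med = float(np.median(other_gaps)) if len(other_gaps) else 0.0
        return max(gap_factor * med, gap_factor * pooled_se, min_separation)

    imax = int(np.argmax(gaps))
    others = np.delete(gaps, imax)
    if gaps[imax] <= threshold(others):
        return [order]
    # two clusters; verify neither splits again under the same rule
    for side in (gaps[:imax], gaps[imax + 1:]):
        if len(side) >= 1:
            j = int(np.argmax(side))
            rest = np.delete(side, j)
            if side[j] > threshold(rest):
                raise TooManyBranchesError(
                    "more than two well-separated attractor branches detected")
    return [order[:imax + 1], order[imax + 1:]]


# --------------------------------------------------------------------------
# surfaces
# --------------------------------------------------------------------------

@dataclass
class NonlinearitySurface:
    """Tabulated effective nonlinearity over (input, noise).

    ``branch_values[k, i, :]`` holds up to two branch means at
    (sigma_grid[k], I_grid[i]); the second entry is NaN where only one
    branch exists.  Branches are ordered by value (lower = fixed-point-like,
    upper = cycle-average-like in the Hodgkin-Huxley convention).
    ``pooled`` is the mean over all initial conditions (a single-valued
    slice used for slope diagnostics).
    """

    model_id: str
    I_grid: np.ndarray
    sigma_grid: np.ndarray
    branch_values: np.ndarray        # (n_sigma, n_I, 2), NaN for absent branch
    branch_stderr: np.ndarray        # same shape
    branch_counts: np.ndarray        # (n_sigma, n_I) number of branches (1 or 2)
    pooled: np.ndarray               # (n_sigma, n_I)
    regimes: List[str]               # per sigma: "I" or "II"
    settings: dict
    seed: int = 0
    warnings: List[str] = field(default_factory=list)
    pooled_voltage: Optional[np.ndarray] = None   # (n_sigma, n_I) mean voltage

    def sigma_index(self, sigma: float) -> int:
        k = int(np.argmin(np.abs(self.sigma_grid - sigma)))
        return k

    def bistable_window(self, sigma: float) -> Optional[Tuple[float, float]]:
        """I-interval with two branches at the slice nearest to sigma."""
        k = self.sigma_index(sigma)
        idx = np.nonzero(self.branch_counts[k] == 2)[0]
        if idx.size == 0:
            return None
        return float(self.I_grid[idx[0]]), float(self.I_grid[idx[-1]])

    def max_slice_slope(self, sigma: float, quantity: str = "voltage") -> float:
        """Maximum |finite-difference slope| of a pooled sigma-slice.

        ``quantity`` is "voltage" (the mean-voltage sigmoid, the natural
        object for the noise-smoothing effect) or "observable" (the stored
        residual nonlinearity).
        """
        k = self.sigma_index(sigma)
        arr = self.pooled[k] if quantity == "observable" else self.pooled_voltage[k]
        return float(np.max(np.abs(np.diff(arr) / np.diff(self.I_grid))))


def build_surface(spec: ModelSpec, I_grid: Sequence[float],
                  sigma_grid: Sequence[float], n_inits: int = 6,
                  settings: Optional[EstimateSettings] = None,
                  seed: int = 0) -> NonlinearitySurface:
    """Estimate the effective nonlinearity on a grid of (input, noise).

    For every grid point the temporal average is computed from ``n_inits``
    dispersed initial conditions (all (I, init) pairs of a noise level are
    simulated as one vectorized batch); the per-init values are clustered
    into one or two branches, and a noise level is labeled regime II iff
    any input shows two branches.
    """
    I_grid = np.asarray(I_grid, dtype=float)
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    if I_grid.size == 0 or sigma_grid.size == 0:
        raise ValueError("grids must be non-empty")
    if n_inits < 2:
        raise ValueError("n_inits must be >= 2")
    if settings is None:
        settings = default_settings(spec)

    nI, nS = len(I_grid), len(sigma_grid)
    values = np.empty((nS, nI, n_inits))
    ses = np.empty((nS, nI, n_inits))
    voltages = np.empty((nS, nI, n_inits))
    warnings: List[str] = []

    rng_init = substream(seed, "surface-inits")
    dispersed = _dispersed_inits(spec, n_inits, rng_init)
    I_batch = np.repeat(I_grid, n_inits)
    init_batch = np.vstack([_anchored_inits(spec, float(I), n_inits, dispersed)
                            for I in I_grid])

    for k, sigma in enumerate(sigma_grid):
        rng = substream(seed, f"surface-noise-{k}")
        mean, se, traces, trace_dt, vbar, _ = _simulate_batch(
            spec, I_batch, float(sigma), init_batch, settings, rng)
        values[k] = mean.reshape(nI, n_inits)
        ses[k] = se.reshape(nI, n_inits)
        voltages[k] = vbar.reshape(nI, n_inits)
        for i in range(nI):
            for j in range(n_inits):
                tr = traces[i * n_inits + j]
                p = measure_period(tr, trace_dt, settings.autocorr_threshold)
                if p is not None and settings.t_average < 5.0 * p:
                    warnings.append(
                        f"sigma={sigma:g} I={I_grid[i]:g}: averaging horizon "
                        f"covers fewer than 5 periods ({p:.3g} ms)")

    span = float(np.ptp(values))
    min_sep = settings.separation_fraction * span if span > 0 else 1e-9

    branch_values = np.full((nS, nI, 2), np.nan)
    branch_stderr = np.full((nS, nI, 2), np.nan)
    counts = np.zeros((nS, nI), dtype=int)
    pooled = values.mean(axis=2)
    regimes: List[str] = []
    for k in range(nS):
        any_two = False
        for i in range(nI):
            clusters = split_branches(values[k, i], ses[k, i], min_sep,
                                      settings.gap_factor)
            counts[k, i] = len(clusters)
            for ci, idx in enumerate(clusters):
                vals = values[k, i][idx]
                branch_values[k, i, ci] = vals.mean()
                spread = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
                branch_stderr[k, i, ci] = max(
                    spread, float(np.sqrt(np.mean(ses[k, i][idx] ** 2))))
            any_two = any_two or len(clusters) == 2
        regimes.append("II" if any_two else "I")

    return NonlinearitySurface(
        model_id=spec.model_id, I_grid=I_grid, sigma_grid=sigma_grid,
        branch_values=branch_values, branch_stderr=branch_stderr,
        branch_counts=counts, pooled=pooled, regimes=regimes,
        settings={**asdict(settings), "n_inits": n_inits}, seed=seed,
        warnings=warnings, pooled_voltage=voltages.mean(axis=2))


def surface_lookup(surface: NonlinearitySurface, I: float, sigma: float,
                   branch: str = "lower", sigma_mode: str = "nearest",
                   strict: bool = False) -> float:
    """Interpolate the tabulated nonlinearity.

    Linear in I within a branch; nearest (default) or linear in sigma.
    Queries are exact at grid nodes.  Extrapolation beyond the grid hull
    raises ``HullError``.  ``branch`` is "lower", "upper" or "pooled"; when
    the requested branch is absent at a node the other branch's value is
    used unless ``strict``.
    """
    I = float(I)
    sigma = float(sigma)
    Ig, Sg = surface.I_grid, surface.sigma_grid
    tol_I = 1e-9 * max(1.0, np.max(np.abs(Ig)))
    tol_S = 1e-9 * max(1.0, np.max(np.abs(Sg)))
    if I < Ig[0] - tol_I or I > Ig[-1] + tol_I:
        raise HullError(f"I={I} outside tabulated range [{Ig[0]}, {Ig[-1]}]")
    if sigma < Sg.min() - tol_S or sigma > Sg.max() + tol_S:
        raise HullError(f"sigma={sigma} outside tabulated range")

    def slice_values(k: int) -> np.ndarray:
        if branch == "pooled":
            return surface.pooled[k]
        col = 0 if branch == "lower" else 1
        vals = surface.branch_values[k, :, col].copy()
        missing = np.isnan(vals)
        if missing.any():
            if strict:
                raise HullError(
                    f"branch {branch!r} absent at some nodes of sigma slice {k}")
            vals[missing] = surface.branch_values[k, missing, 0]
        return vals

    def interp_I(k: int) -> float:
        return float(np.interp(np.clip(I, Ig[0], Ig[-1]), Ig, slice_values(k)))

    if sigma_mode == "nearest" or len(Sg) == 1:
        return interp_I(surface.sigma_index(sigma))
    k_hi = int(np.searchsorted(Sg, sigma))
    k_hi = min(max(k_hi, 1), len(Sg) - 1)
    k_lo = k_hi - 1
    t = (sigma - Sg[k_lo]) / (Sg[k_hi] - Sg[k_lo])
    t = float(np.clip(t, 0.0, 1.0))
    return (1 - t) * interp_I(k_lo) + t * interp_I(k_hi)


# --------------------------------------------------------------------------
# deterministic hysteresis sweep
# --------------------------------------------------------------------------

@dataclass
class SweepPoint:
    I: float
    direction: str                 # "forward" | "backward"
    value: float                   # time-averaged observable r
    mean_voltage: float
    period: Optional[float]        # ms; None = stationary
    settled: bool


@dataclass
class BranchSystem:
    """Stable fixed-point and cycle branches of the effective nonlinearity.

    Interpolants return the observable value (the quantity the reduced
    model's nonlinear term uses).  ``fold_fp`` is the largest input at
    which the fixed point still exists; ``fold_cycle`` the smallest input
    at which the cycle exists.  In regime II the two validity intervals
    overlap exactly on the bistable window.
    """

    I_fp: np.ndarray
    r_fp: np.ndarray
    v_fp: np.ndarray
    I_cycle: np.ndarray
    r_cycle: np.ndarray
    v_cycle: np.ndarray
    freq_cycle: np.ndarray            # Hz
    fold_fp: Optional[float]
    fold_cycle: Optional[float]
    points: List[SweepPoint] = field(default_factory=list)
    windows: List[Tuple[float, float]] = field(default_factory=list)

    @staticmethod
    def _eval(I: float, xs: np.ndarray, ys: np.ndarray, name: str) -> float:
        """Linear interpolation with a one-grid-cell extrapolation margin.

        The margin lets trial integrator stages evaluate the branch just
        past its fold before the fold-crossing event is located; beyond it
        the query is a genuine hull violation.
        """
        if xs.size == 0:
            raise ValueError(f"no {name} branch in sweep range")
        margin = float(np.max(np.diff(xs))) if xs.size > 1 else 1e-9
        if not (xs[0] - margin <= I <= xs[-1] + margin):
            raise HullError(f"I={I} outside {name} branch [{xs[0]}, {xs[-1]}]")
        if xs.size == 1:
            return float(ys[0])
        if I < xs[0]:
            return float(ys[0] + (ys[1] - ys[0]) / (xs[1] - xs[0]) * (I - xs[0]))
        if I > xs[-1]:
            return float(ys[-1] + (ys[-1] - ys[-2]) / (xs[-1] - xs[-2]) * (I - xs[-1]))
        return float(np.interp(I, xs, ys))

    def fp(self, I: float) -> float:
        return self._eval(I, self.I_fp, self.r_fp, "fixed-point")

    def cycle(self, I: float) -> float:
        return self._eval(I, self.I_cycle, self.r_cycle, "cycle")

    @property
    def bistable_window(self) -> Optional[Tuple[float, float]]:
        """Widest input interval where a fixed point and a cycle coexist."""
        if not self.windows:
            return None
        return max(self.windows, key=lambda w: w[1] - w[0])

    def onset_frequency(self) -> Optional[float]:
        """Frequency (Hz) of the cycle at its lowest-input appearance."""
        if self.I_cycle.size == 0:
            return None
        return float(self.freq_cycle[0])


def _settle_and_average(spec, I_pair, states, settings):
    mean, se, traces, trace_dt, vbar, final = _simulate_batch(
        spec, np.asarray(I_pair, dtype=float), 0.0, states, settings, None)
    return mean, vbar, traces, trace_dt, final


def deterministic_sweep(spec: ModelSpec, I_grid: Sequence[float],
                        settings: Optional[EstimateSettings] = None
                        ) -> BranchSystem:
    """Noise-free bifurcation scan via forward and backward sweeps.

    The forward sweep increases I, continuing the integration state from
    the previous input (so it tracks the fixed-point branch until it
    disappears); the backward sweep decreases I (tracking the cycle down to
    its fold).  Points where neither stationarity nor a period is detected
    are flagged unsettled and excluded from the branch interpolants.
    """
    I_grid = np.asarray(I_grid, dtype=float)
    if np.any(np.diff(I_grid) <= 0):
        raise ValueError("I-grid must be sorted increasing")
    if settings is None:
        settings = default_settings(spec)

    # initial states: forward from the low-I fixed point (or default guess),
    # backward from a depolarized state that lands on whatever attractor
    # exists at the top of the grid.
    try:
        st_f = fixed_point(spec, float(I_grid[0]))
    except FixedPointError:
        st_f = _dispersed_inits(spec, 1, substream(0, "sweep"))[0]
    st_b = _dispersed_inits(spec, 2, substream(1, "sweep"))[1]
    states = np.vstack([st_f, st_b])

    n = len(I_grid)
    points: List[SweepPoint] = []
    fwd: List[SweepPoint] = [None] * n
    bwd: List[SweepPoint] = [None] * n
    for k in range(n):
        I_pair = (I_grid[k], I_grid[n - 1 - k])
        # settle (continuation from the previous attractor state), then average
        mean, vbar, traces, trace_dt, states = _settle_and_average(
            spec, I_pair, states, settings)
        for b, (direction, idx) in enumerate((("forward", k), ("backward", n - 1 - k))):
            period, _, settled = classify_trace(
                traces[b], trace_dt, float(mean[b]), settings.autocorr_threshold)
            pt = SweepPoint(I=float(I_pair[b]), direction=direction,
                            value=float(mean[b]), mean_voltage=float(vbar[b]),
                            period=period, settled=settled)
            points.append(pt)
            (fwd if direction == "forward" else bwd)[idx] = pt

    fp_pts = sorted((p for p in points if p.settled and p.period is None),
                    key=lambda p: p.I)
    cyc_pts = sorted((p for p in points if p.settled and p.period is not None),
                     key=lambda p: p.I)

    def dedupe(pts):
        out = {}
        for p in pts:
            out.setdefault(p.I, []).append(p)
        Is = sorted(out)
        vals = [float(np.mean([q.value for q in out[i]])) for i in Is]
        volts = [float(np.mean([q.mean_voltage for q in out[i]])) for i in Is]
        pers = [float(np.mean([q.period for q in out[i] if q.period]))
                if any(q.period for q in out[i]) else None for i in Is]
        return np.array(Is), np.array(vals), np.array(volts), pers

    I_fp, r_fp, v_fp, _ = dedupe(fp_pts)
    I_cy, r_cy, v_cy, per_cy = dedupe(cyc_pts)
    freq = np.array([1000.0 / p if p else np.nan for p in per_cy])

    # bistability: contiguous grid runs where both attractors were observed
    both = np.array([I for I in I_grid
                     if I in set(I_fp.tolist()) and I in set(I_cy.tolist())])
    windows: List[Tuple[float, float]] = []
    if both.size:
        grid_pos = {I: k for k, I in enumerate(I_grid.tolist())}
        run = [both[0]]
        for I in both[1:]:
            if grid_pos[I] == grid_pos[run[-1]] + 1:
                run.append(I)
            else:
                windows.append((float(run[0]), float(run[-1])))
                run = [I]
        windows.append((float(run[0]), float(run[-1])))

    # fold inputs delimiting the principal (widest) bistable window; the
    # fixed point disappears at the window's top, the cycle at its bottom
    fold_fp = fold_cycle = None
    if windows:
        main = max(windows, key=lambda w: w[1] - w[0])
        fold_cycle, fold_fp = main

    return BranchSystem(
        I_fp=I_fp, r_fp=r_fp, v_fp=v_fp,
        I_cycle=I_cy, r_cycle=r_cy, v_cycle=v_cy, freq_cycle=freq,
        fold_fp=fold_fp, fold_cycle=fold_cycle,
        points=points, windows=windows)


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

def surface_to_json(surface: NonlinearitySurface) -> str:
    d = {
        "model_id": surface.model_id,
        "I_grid": surface.I_grid.tolist(),
        "sigma_grid": surface.sigma_grid.tolist(),
        "branch_values": surface.branch_values.tolist(),
        "branch_stderr": surface.branch_stderr.tolist(),
        "branch_counts": surface.branch_counts.tolist(),
        "pooled": surface.pooled.tolist(),
        "regimes": surface.regimes,
        "settings": surface.settings,
        "seed": surface.seed,
        "warnings": surface.warnings,
        "pooled_voltage": (surface.pooled_voltage.tolist()
                           if surface.pooled_voltage is not None else None),
    }
    return json.dumps(d, indent=1)


def surface_from_json(text: str) -> NonlinearitySurface:
    d = json.loads(text)
    return NonlinearitySurface(
        model_id=d["model_id"],
        I_grid=np.array(d["I_grid"]),
        sigma_grid=np.array(d["sigma_grid"]),
        branch_values=np.array(d["branch_values"]),
        branch_stderr=np.array(d["branch_stderr"]),
        branch_counts=np.array(d["branch_counts"], dtype=int),
        pooled=np.array(d["pooled"]),
        regimes=list(d["regimes"]),
        settings=d.get("settings", {}),
        seed=d.get("seed", 0),
        warnings=d.get("warnings", []),
        pooled_voltage=(np.array(d["pooled_voltage"])
                        if d.get("pooled_voltage") is not None else None))


def surface_to_csv(surface: NonlinearitySurface, path: str) -> None:
    import pandas as pd
    rows = []
    for k, s in enumerate(surface.sigma_grid):
        for i, I in enumerate(surface.I_grid):
            for ci in range(surface.branch_counts[k, i]):
                rows.append(dict(I=I, sigma=s, branch=("lower", "upper")[ci],
                                 value=surface.branch_values[k, i, ci],
                                 stderr=surface.branch_stderr[k, i, ci]))
    pd.DataFrame(rows).to_csv(path, index=False)
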