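"""Macroscopic (reduced) population equations.

For P populations the network of order N*P stochastic equations collapses
to a deterministic system of order P (plus one exponential-memory state
per population realizing the delayed linear term, and one synaptic filter
state per population).  Per population alpha::

    d nu/dt  = inst * nu + (amp/rate) * m + gain * I_eff + S(I_eff)
    d m/dt   = rate * (nu + offset - m)          (linear-part memory)
    d g/dt   = (nu - g) / tau_s                  (synaptic filter)

    I_eff_alpha(t) = I_alpha(t) + sum_beta J_mean[alpha, beta] * g_beta(t)

where (inst, amp, rate, offset, gain) come from the model's LinearPart and
S is the effective nonlinearity (analytic sigmoid or a tabulated-surface
lookup at fixed noise level).  The memory state m is the unit-gain
exponential filter of nu + offset; implementing the kernel as this
auxiliary ODE is exact for exponential kernels.

Regime I (single-branch S) integrates the ODE directly with fixed-step
RK4.  Regime II carries a per-population attractor label (fixed point or
cycle); the nonlinearity used at time t is the labeled branch of a
BranchSystem, and when the effective input crosses the fold at which that
branch ends, the label flips (event located by bisection within the step)
while nu itself is carried continuously.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .neuron_models import ModelSpec, LinearPart, linear_part, fixed_point
from .network_sim import _as_input_fn
from .macro_activity import MacroTrajectory
from .effective_nonlinearity import BranchSystem, HullError

__all__ = [
    "ReducedConfig",
    "AttractorState",
    "SwitchEvent",
    "effective_input",
    "integrate_regime1",
    "integrate_regime2",
    "stationary_solution",
    "reduced_config_for_model",
]


@dataclass
class ReducedConfig:
    """Configuration of the macroscopic system."""

    P: int
    J_mean: np.ndarray                       # (P, P)
    tau_s: float
    linear_parts: List[LinearPart]           # one per population
    nonlinearities: List[Callable]           # S_alpha(I) for regime I
    inputs: object                           # callable t -> (P,) or constants
    dt: float = 0.05
    T_total: float = 500.0
    nu0: Optional[np.ndarray] = None
    mem0: Optional[np.ndarray] = None        # default: nu0 + kernel offset
    filter0: Optional[np.ndarray] = None     # default: nu0
    regime: str = "I"
    branch_systems: Optional[List[BranchSystem]] = None
    initial_labels: Optional[List[str]] = None
    filter_effective_input: bool = True      # pass nu through eta before J

    def __post_init__(self):
        if self.dt <= 0 or self.tau_s <= 0:
            raise ValueError("dt and tau_s must be positive")
        self.J_mean = np.array(self.J_mean, dtype=float).reshape(self.P, self.P)
        if len(self.linear_parts) != self.P:
            raise ValueError("need one LinearPart per population")
        if self.regime == "I" and len(self.nonlinearities) != self.P:
            raise ValueError("need one nonlinearity per population")
        if self.regime == "II" and (self.branch_systems is None
                                    or len(self.branch_systems) != self.P):
            raise ValueError("regime II needs one BranchSystem per population")
        self.nu0 = (np.zeros(self.P) if self.nu0 is None
                    else np.asarray(self.nu0, dtype=float).reshape(self.P))
        if self.mem0 is None:
            self.mem0 = self.nu0 + np.array(
                [lp.kernel_input_offset for lp in self.linear_parts])
        else:
            self.mem0 = np.asarray(self.mem0, dtype=float).reshape(self.P)
        self.filter0 = (self.nu0.copy() if self.filter0 is None
                        else np.asarray(self.filter0, dtype=float).reshape(self.P))

    def input_fn(self):
        return _as_input_fn(self.inputs, self.P)


@dataclass
class SwitchEvent:
    t: float
    population: int
    from_label: str
    to_label: str


@dataclass
class AttractorState:
    labels: List[str]
    events: List[SwitchEvent] = field(default_factory=list)


def effective_input(nu_or_filtered: np.ndarray, inputs_t: np.ndarray,
                    J_mean: np.ndarray) -> np.ndarray:
    """I_eff = external input + mean-connectivity-weighted filtered activity.

    ``nu_or_filtered`` is the synaptically filtered activity g (or nu itself
    when the filter is bypassed).
    """
    return np.asarray(inputs_t, dtype=float) + J_mean @ np.asarray(nu_or_filtered, float)


def _coef_arrays(config: ReducedConfig):
    inst = np.array([lp.instantaneous_coeff for lp in config.linear_parts])
    amp = np.array([lp.kernel_amplitude for lp in config.linear_parts])
    rate = np.array([lp.kernel_rate for lp in config.linear_parts])
    off = np.array([lp.kernel_input_offset for lp in config.linear_parts])
    gain = np.array([lp.input_gain for lp in config.linear_parts])
    memc = np.where(rate > 0, amp / np.where(rate > 0, rate, 1.0), 0.0)
    return inst, memc, rate, off, gain


def _make_rhs(config: ReducedConfig, S_of: Callable[[int, float], float]):
    inst, memc, rate, off, gain = _coef_arrays(config)
    J = config.J_mean
    P = config.P
    input_fn = config.input_fn()
    use_filter = config.filter_effective_input

    def rhs(t: float, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        nu = y[:P]
        m = y[P:2 * P]
        g = y[2 * P:]
        carrier = g if use_filter else nu
        I_eff = effective_input(carrier, input_fn(t), J)
        S = np.array([S_of(a, float(I_eff[a])) for a in range(P)])
        dnu = inst * nu + memc * m + gain * I_eff + S
        dm = rate * (nu + off - m)
        dg = (nu - g) / config.tau_s
        return np.concatenate([dnu, dm, dg]), I_eff

    return rhs


def _rk4_step(rhs, t, y, h):
    k1, _ = rhs(t, y)
    k2, _ = rhs(t + h / 2, y + h / 2 * k1)
    k3, _ = rhs(t + h / 2, y + h / 2 * k2)
    k4, _ = rhs(t + h, y + h * k3)
    return y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


def integrate_regime1(config: ReducedConfig) -> MacroTrajectory:
    """Fixed-step RK4 integration of the single-branch macroscopic ODE."""
    if config.regime != "I":
        raise ValueError("config.regime must be 'I'")

    def S_of(a: int, I: float) -> float:
        try:
            return config.nonlinearities[a](I)
        except HullError as e:
            raise HullError(f"population {a}: {e}") from e

    rhs = _make_rhs(config, S_of)
    P = config.P
    y = np.concatenate([config.nu0, config.mem0, config.filter0])
    n = int(round(config.T_total / config.dt))
    time = np.arange(n + 1) * config.dt
    nu = np.empty((P, n + 1))
    nu[:, 0] = y[:P]
    for k in range(n):
        t = k * config.dt
        try:
            y = _rk4_step(rhs, t, y, config.dt)
        except HullError as e:
            raise HullError(f"at t={t:.6g} ms: {e}") from e
        nu[:, k + 1] = y[:P]
    return MacroTrajectory(time=time, nu=nu, provenance="reduced-model")


def integrate_regime2(config: ReducedConfig
                      ) -> Tuple[MacroTrajectory, AttractorState]:
    """Attractor-tracking integration for bistable (regime II) nonlinearities.

    Each population pursues its current attractor branch while the branch
    exists, and switches (with nu carried continuously) when the effective
    input crosses the fold at which the branch disappears.
    """
    if config.regime != "II":
        raise ValueError("config.regime must be 'II'")
    bs = config.branch_systems
    P = config.P

    labels = list(config.initial_labels) if config.initial_labels else None
    input_fn = config.input_fn()
    if labels is None:
        carrier = config.filter0 if config.filter_effective_input else config.nu0
        I0 = effective_input(carrier, input_fn(0.0), config.J_mean)
        labels = []
        for a in range(P):
            fold_fp = bs[a].fold_fp
            labels.append("fp" if (fold_fp is None or I0[a] <= fold_fp) else "cycle")

    state = AttractorState(labels=labels)

    def S_of(a: int, I: float) -> float:
        return bs[a].fp(I) if state.labels[a] == "fp" else bs[a].cycle(I)

    rhs = _make_rhs(config, S_of)

    def crossing(y, t) -> Optional[int]:
        """Index of a population whose current branch has disappeared."""
        g = y[2 * P:]
        carrier = g if config.filter_effective_input else y[:P]
        I_eff = effective_input(carrier, input_fn(t), config.J_mean)
        for a in range(P):
            if state.labels[a] == "fp":
                if bs[a].fold_fp is not None and I_eff[a] > bs[a].fold_fp:
                    return a
            else:
                if bs[a].fold_cycle is not None and I_eff[a] < bs[a].fold_cycle:
                    return a
        return None

    y = np.concatenate([config.nu0, config.mem0, config.filter0])
    n = int(round(config.T_total / config.dt))
    time = np.arange(n + 1) * config.dt
    nu = np.empty((P, n + 1))
    nu[:, 0] = y[:P]

    for k in range(n):
        t = k * config.dt
        remaining = config.dt
        guard = 0
        while remaining > 1e-12 and guard < 8:
            y_try = _rk4_step(rhs, t, y, remaining)
            a = crossing(y_try, t + remaining)
            if a is None:
                y = y_try
                t += remaining
                remaining = 0.0
                break
            # bisect for the crossing time within (0, remaining]
            lo, hi = 0.0, remaining
            for _ in range(40):
                mid = 0.5 * (lo + hi)
                y_mid = _rk4_step(rhs, t, y, mid) if mid > 0 else y
                if crossing(y_mid, t + mid) is None:
                    lo = mid
                else:
                    hi = mid
            y = _rk4_step(rhs, t, y, hi) if hi > 0 else y
            t += hi
            remaining -= hi
            old = state.labels[a]
            new = "cycle" if old == "fp" else "fp"
            state.labels[a] = new
            state.events.append(SwitchEvent(t=float(t), population=a,
                                            from_label=old, to_label=new))
            guard += 1
        nu[:, k + 1] = y[:P]

    macro = MacroTrajectory(time=time, nu=nu, provenance="reduced-model")
    return macro, state


def stationary_solution(config: ReducedConfig, I: Sequence[float] | float,
                        bracket: Tuple[float, float] = (-20.0, 20.0),
                        n_scan: int = 400) -> List[Tuple[np.ndarray, bool]]:
    """Equilibria of the closed-loop regime I system under constant input.

    At stationarity the memory and filter states equal their driven values,
    so the fixed-point condition reduces to G(nu) = 0 with::

        G_a(nu) = (inst_a + memc_a) * nu_a + memc_a * off_a
                  + gain_a * I_eff_a + S_a(I_eff_a),  I_eff = I + J nu

    For P = 1 all roots in ``bracket`` are found by sign-change scanning
    plus Brent refinement; for P > 1 a root search is started from a grid
    of diagonal guesses.  Stability is judged from the eigenvalues of the
    numerical Jacobian of the full (3P-dimensional) dynamical system.
    """
    from scipy.optimize import brentq, root as sp_root

    if config.regime != "I":
        raise ValueError("stationary_solution requires regime I")
    inst, memc, rate, off, gain = _coef_arrays(config)
    J = config.J_mean
    P = config.P
    I = np.broadcast_to(np.asarray(I, dtype=float), (P,))

    def G(nu: np.ndarray) -> np.ndarray:
        nu = np.asarray(nu, dtype=float).reshape(P)
        I_eff = I + J @ nu
        S = np.array([config.nonlinearities[a](float(I_eff[a])) for a in range(P)])
        return (inst + memc) * nu + memc * off + gain * I_eff + S

    # full-system Jacobian for the stability tag
    cfg_const = ReducedConfig(
        P=P, J_mean=J, tau_s=config.tau_s, linear_parts=config.linear_parts,
        nonlinearities=config.nonlinearities, inputs=I, dt=config.dt,
        T_total=config.T_total, regime="I",
        filter_effective_input=config.filter_effective_input)
    rhs = _make_rhs(cfg_const, lambda a, x: config.nonlinearities[a](x))

    def stable(nu_star: np.ndarray) -> bool:
        y0 = np.concatenate([nu_star, nu_star + off, nu_star])
        f0, _ = rhs(0.0, y0)
        eps = 1e-6
        Jm = np.empty((3 * P, 3 * P))
        for j in range(3 * P):
            yp = y0.copy()
            yp[j] += eps
            fp_, _ = rhs(0.0, yp)
            Jm[:, j] = (fp_ - f0) / eps
        return bool(np.all(np.linalg.eigvals(Jm).real < 1e-8))

    roots: List[Tuple[np.ndarray, bool]] = []
    if P == 1:
        xs = np.linspace(bracket[0], bracket[1], n_scan)
        vals = []
        ok = []
        for x in xs:
            try:
                vals.append(float(G(np.array([x]))[0]))
                ok.append(True)
            except HullError:
                vals.append(np.nan)
                ok.append(False)
        vals = np.array(vals)
        found = []
        for i in range(len(xs) - 1):
            if not (ok[i] and ok[i + 1]):
                continue
            if vals[i] == 0.0:
                found.append(xs[i])
            elif vals[i] * vals[i + 1] < 0:
                r = brentq(lambda x: float(G(np.array([x]))[0]), xs[i], xs[i + 1],
                           xtol=1e-12)
                found.append(r)
        for r in found:
            nu_star = np.array([r])
            roots.append((nu_star, stable(nu_star)))
        if not roots:
            raise ValueError("no stationary solution found in bracket")
        return roots

    guesses = [np.full(P, x) for x in np.linspace(bracket[0], bracket[1], 9)]
    seen: List[np.ndarray] = []
    for g0 in guesses:
        try:
            sol = sp_root(G, g0, method="hybr", tol=1e-12)
        except HullError:
            continue
        # hybr can report failure on non-smooth nonlinearities even at a
        # machine-precision root: judge by the residual
        if np.max(np.abs(G(sol.x))) > 1e-8:
            continue
        if any(np.allclose(sol.x, s, atol=1e-6) for s in seen):
            continue
        seen.append(sol.x.copy())
        roots.append((sol.x.copy(), stable(sol.x)))
    if not roots:
        raise ValueError("no stationary solution found from scanned guesses")
    return roots


def reduced_config_for_model(spec: ModelSpec, P: int, J_mean, tau_s: float,
                             nonlinearities: Sequence[Callable] | Callable,
                             inputs, dt: float = 0.05, T_total: float = 500.0,
                             nu0: Optional[np.ndarray] = None,
                             **kwargs) -> ReducedConfig:
    """Convenience constructor wiring a neuron model's linear part in.

    Defaults the initial activity to the decoupled fixed-point voltage at
    the t = 0 input of each population.
    """
    lp = linear_part(spec)
    if callable(nonlinearities):
        nonlinearities = [nonlinearities] * P
    if nu0 is None:
        I0 = _as_input_fn(inputs, P)(0.0)
        nu0 = np.empty(P)
        for a in range(P):
            try:
                nu0[a] = fixed_point(spec, float(I0[a]))[spec.voltage_index]
            except Exception:
                nu0[a] = 0.0
    return ReducedConfig(P=P, J_mean=J_mean, tau_s=tau_s,
                         linear_parts=[lp] * P,
                         nonlinearities=list(nonlinearities),
                         inputs=inputs, dt=dt, T_total=T_total, nu0=nu0,
                         **kwargs)
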