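"""Single-neuron models and their linear/nonlinear split.

Three excitable neuron models are supported, all parametrized so that the
time unit is one millisecond and voltage is in mV:

* ``mckean`` -- piecewise-linear caricature of the FitzHugh-Nagumo model.
  Voltage nullcline is an N-shaped continuous piecewise-linear curve with
  three segments (decreasing outer branches, increasing middle branch),
  which makes relaxation-oscillation transit times computable in closed
  form.  Dynamics::

      v' = (f(v) - w) / eps + I
      w' = c * (v - b * w)

* ``fhn`` -- classic FitzHugh-Nagumo::

      v' = c1*v - c3*v**3 - w + I
      w' = (v + a - b * w) / tau_w

* ``hh`` -- original Hodgkin-Huxley squid-axon model (resting potential
  near 0 mV convention)::

      C V' = I - gNa m^3 h (V - ENa) - gK n^4 (V - EK) - gL (V - EL)
      x'   = alpha_x(V) (1 - x) - beta_x(V) x   for x in {m, h, n}

For the macroscopic reduction each model's voltage drift is split into a
*linear part* L (an instantaneous decay plus, for the two-variable models,
an exponential-memory term arising from implicit integration of the
adaptation variable) and a residual observable ``r`` whose long-run
temporal average defines the effective nonlinearity S.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Dict, Sequence, Tuple

import numpy as np
import yaml

__all__ = [
    "McKeanParams",
    "FHNParams",
    "HHParams",
    "LinearPart",
    "ModelSpec",
    "FixedPointError",
    "drift",
    "observable",
    "noise_amplitudes",
    "fixed_point",
    "linear_part",
    "build_model",
    "register_model",
    "spec_to_yaml",
    "spec_from_yaml",
    "hh_gating_steady_state",
    "MODEL_REGISTRY",
]


# --------------------------------------------------------------------------
# parameter records
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class McKeanParams:
    """Piecewise-linear caricature parameters.

    The voltage nullcline function is::

        f(v) = slope_mid * v                          for v_lo <= v <= v_hi
        f(v) = slope_mid*v_lo + slope_outer*(v - v_lo)   for v < v_lo
        f(v) = slope_mid*v_hi + slope_outer*(v - v_hi)   for v > v_hi

    ``slope_outer`` must be negative and ``slope_mid`` positive so the
    nullcline is N-shaped: the outer branches are the attracting slow
    manifolds, the middle branch is repelling.
    """

    v_lo: float = -1.0
    v_hi: float = 1.0
    slope_mid: float = 2.0 / 3.0
    slope_outer: float = -1.0
    b: float = 0.5      # adaptation coupling (w-nullcline is w = v / b)
    c: float = 0.1      # adaptation rate, ms^-1 (slow: c << 1/eps)
    eps: float = 0.5    # voltage timescale, ms (fast)

    def __post_init__(self):
        if not (self.v_lo < self.v_hi):
            raise ValueError("require v_lo < v_hi")
        if not (self.slope_mid > 0 > self.slope_outer):
            raise ValueError("middle branch slope must be positive, outer negative")
        if self.eps <= 0 or self.c <= 0 or self.b <= 0:
            raise ValueError("eps, c, b must be positive")

    def f(self, v):
        """Piecewise-linear voltage nullcline function."""
        v = np.asarray(v, dtype=float)
        mid = self.slope_mid * v
        lo = self.slope_mid * self.v_lo + self.slope_outer * (v - self.v_lo)
        hi = self.slope_mid * self.v_hi + self.slope_outer * (v - self.v_hi)
        return np.where(v < self.v_lo, lo, np.where(v > self.v_hi, hi, mid))


@dataclass(frozen=True)
class FHNParams:
    """FitzHugh-Nagumo parameters (classic values by default).

    ``k`` is the reduction slope: the absolute slope of the straight line
    approximating the decreasing negative branch of the cubic, used as the
    instantaneous coefficient of the linear part.  If not given it defaults
    to the secant slope of the cubic between the left knee and twice the
    knee voltage, which is ``(4/3) * c1``.
    """

    c1: float = 1.0
    c3: float = 1.0 / 3.0
    a: float = 0.7       # adaptation offset
    b: float = 0.8       # adaptation gain
    tau_w: float = 12.5  # adaptation timescale, ms
    k: float | None = None

    def __post_init__(self):
        if self.tau_w <= 0:
            raise ValueError("tau_w must be positive")
        if self.c1 <= 0 or self.c3 <= 0:
            raise ValueError("cubic coefficients must be positive")
        if self.k is not None and self.k <= 0:
            raise ValueError("k must be positive")

    @property
    def reduction_slope(self) -> float:
        if self.k is not None:
            return self.k
        return 4.0 * self.c1 / 3.0

    def f(self, v):
        v = np.asarray(v, dtype=float)
        return self.c1 * v - self.c3 * v ** 3


def _vtrap(x):
    """x / (exp(x) - 1), continuous at 0."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-9
    out[small] = 1.0
    xs = x[~small]
    out[~small] = xs / np.expm1(xs)
    return out


def hh_alpha_m(V):
    return _vtrap((25.0 - np.asarray(V, float)) / 10.0)


def hh_beta_m(V):
    return 4.0 * np.exp(-np.asarray(V, float) / 18.0)


def hh_alpha_h(V):
    return 0.07 * np.exp(-np.asarray(V, float) / 20.0)


def hh_beta_h(V):
    return 1.0 / (np.exp((30.0 - np.asarray(V, float)) / 10.0) + 1.0)


def hh_alpha_n(V):
    return 0.1 * _vtrap((10.0 - np.asarray(V, float)) / 10.0)


def hh_beta_n(V):
    return 0.125 * np.exp(-np.asarray(V, float) / 80.0)


@dataclass(frozen=True)
class HHParams:
    """Original Hodgkin-Huxley squid-axon parameters (rest near 0 mV)."""

    C: float = 1.0
    gNa: float = 120.0
    gK: float = 36.0
    gL: float = 0.3
    ENa: float = 115.0
    EK: float = -12.0
    EL: float = 10.613
    alpha_m: Callable = field(default=hh_alpha_m, repr=False, compare=False)
    beta_m: Callable = field(default=hh_beta_m, repr=False, compare=False)
    alpha_h: Callable = field(default=hh_alpha_h, repr=False, compare=False)
    beta_h: Callable = field(default=hh_beta_h, repr=False, compare=False)
    alpha_n: Callable = field(default=hh_alpha_n, repr=False, compare=False)
    beta_n: Callable = field(default=hh_beta_n, repr=False, compare=False)

    def __post_init__(self):
        for name in ("C", "gNa", "gK", "gL"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class LinearPart:
    """Linear part L of a neuron model's voltage dynamics.

    The contribution of L to the macroscopic drift of the activity nu is::

        L[nu](t) = instantaneous_coeff * nu(t)
                 + kernel_amplitude * int_0^inf exp(-kernel_rate*u)
                                      * (nu(t-u) + kernel_input_offset) du

    ``input_gain`` is the coefficient with which the external/effective
    input current enters the voltage equation (1/C for Hodgkin-Huxley,
    1 otherwise).
    """

    instantaneous_coeff: float    # ms^-1
    kernel_amplitude: float = 0.0  # ms^-2
    kernel_rate: float = 0.0       # ms^-1
    kernel_input_offset: float = 0.0
    input_gain: float = 1.0

    def __post_init__(self):
        if self.kernel_amplitude != 0.0 and self.kernel_rate <= 0.0:
            raise ValueError("kernel_rate must be positive when kernel_amplitude != 0")


_PARAM_TYPES = {"mckean": McKeanParams, "fhn": FHNParams, "hh": HHParams}
_STATE_DIMS = {"mckean": 2, "fhn": 2, "hh": 4}


@dataclass(frozen=True)
class ModelSpec:
    """A neuron model plus noise configuration.

    ``noise_V`` is the white-noise amplitude on the voltage (mV ms^-1/2);
    ``noise_aux`` gives one amplitude per auxiliary coordinate (may be
    zeros; Hodgkin-Huxley gating variables are clipped to [0, 1] after
    each stochastic step by the integrators).
    """

    model_id: str
    params: object
    noise_V: float = 0.0
    noise_aux: Tuple[float, ...] = ()
    voltage_index: int = 0

    def __post_init__(self):
        if self.model_id not in _DRIFT_DISPATCH:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        dim = self.state_dim
        if dim < 2:
            raise ValueError("state_dim must be >= 2")
        if not (0 <= self.voltage_index < dim):
            raise ValueError("voltage_index out of range")
        aux = tuple(float(a) for a in self.noise_aux) or (0.0,) * (dim - 1)
        if len(aux) != dim - 1:
            raise ValueError("noise_aux must have state_dim - 1 entries")
        if self.noise_V < 0 or any(a < 0 for a in aux):
            raise ValueError("noise amplitudes must be nonnegative")
        object.__setattr__(self, "noise_aux", aux)

    @property
    def state_dim(self) -> int:
        return _STATE_DIMS.get(self.model_id) or _EXTRA_DIMS[self.model_id]


class FixedPointError(RuntimeError):
    """Raised when root-finding on the drift does not converge."""


# --------------------------------------------------------------------------
# drift / observable dispatch
# --------------------------------------------------------------------------

def _mckean_drift(p: McKeanParams, state, I):
    v = state[..., 0]
    w = state[..., 1]
    dv = (p.f(v) - w) / p.eps + I
    dw = p.c * (v - p.b * w)
    return np.stack([dv, dw], axis=-1)


def _mckean_observable(p: McKeanParams, state):
    v = state[..., 0]
    return (p.f(v) - p.slope_outer * v) / p.eps


def _fhn_drift(p: FHNParams, state, I):
    v = state[..., 0]
    w = state[..., 1]
    dv = p.f(v) - w + I
    dw = (v + p.a - p.b * w) / p.tau_w
    return np.stack([dv, dw], axis=-1)


def _fhn_observable(p: FHNParams, state):
    v = state[..., 0]
    return p.f(v) + p.reduction_slope * v


def _hh_drift(p: HHParams, state, I):
    V = state[..., 0]
    m = state[..., 1]
    h = state[..., 2]
    n = state[..., 3]
    ina = p.gNa * m ** 3 * h * (V - p.ENa)
    ik = p.gK * n ** 4 * (V - p.EK)
    il = p.gL * (V - p.EL)
    dV = (I - ina - ik - il) / p.C
    dm = p.alpha_m(V) * (1.0 - m) - p.beta_m(V) * m
    dh = p.alpha_h(V) * (1.0 - h) - p.beta_h(V) * h
    dn = p.alpha_n(V) * (1.0 - n) - p.beta_n(V) * n
    return np.stack([dV, dm, dh, dn], axis=-1)


def _hh_observable(p: HHParams, state):
    V = state[..., 0]
    m = state[..., 1]
    h = state[..., 2]
    n = state[..., 3]
    ina = p.gNa * m ** 3 * h * (V - p.ENa)
    ik = p.gK * n ** 4 * (V - p.EK)
    return (-ina - ik + p.gL * p.EL) / p.C


def _mckean_linear_part(p: McKeanParams) -> LinearPart:
    # implicit integration of w' = c (v - b w) gives
    # w(t) = c * int exp(-b c (t-s)) v(s) ds  (plus decaying transient),
    # entering the voltage equation as -w/eps.
    return LinearPart(
        instantaneous_coeff=p.slope_outer / p.eps,
        kernel_amplitude=-p.c / p.eps,
        kernel_rate=p.b * p.c,
    )


def _fhn_linear_part(p: FHNParams) -> LinearPart:
    return LinearPart(
        instantaneous_coeff=-p.reduction_slope,
        kernel_amplitude=-1.0 / p.tau_w,
        kernel_rate=p.b / p.tau_w,
        kernel_input_offset=p.a,
    )


def _hh_linear_part(p: HHParams) -> LinearPart:
    # no delayed linear term can be split off the gating dynamics; use the
    # instantaneous leak decay only.
    return LinearPart(instantaneous_coeff=-p.gL / p.C, input_gain=1.0 / p.C)


_DRIFT_DISPATCH: Dict[str, Callable] = {
    "mckean": _mckean_drift,
    "fhn": _fhn_drift,
    "hh": _hh_drift,
}
_OBSERVABLE_DISPATCH: Dict[str, Callable] = {
    "mckean": _mckean_observable,
    "fhn": _fhn_observable,
    "hh": _hh_observable,
}
_LINEAR_DISPATCH: Dict[str, Callable] = {
    "mckean": _mckean_linear_part,
    "fhn": _fhn_linear_part,
    "hh": _hh_linear_part,
}
_EXTRA_DIMS: Dict[str, int] = {}


def register_model(model_id: str, state_dim: int, drift_fn: Callable,
                   observable_fn: Callable | None = None,
                   linear_part_fn: Callable | None = None) -> None:
    """Register a custom model (used for test doubles and extensions).

    ``drift_fn(params, state, I)`` must be vectorized over leading axes.
    """
    _DRIFT_DISPATCH[model_id] = drift_fn
    _EXTRA_DIMS[model_id] = state_dim
    if observable_fn is not None:
        _OBSERVABLE_DISPATCH[model_id] = observable_fn
    if linear_part_fn is not None:
        _LINEAR_DISPATCH[model_id] = linear_part_fn


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------

def drift(spec: ModelSpec, state, I):
    """Deterministic part of d(state)/dt.

    ``state`` has shape (..., state_dim); ``I`` is scalar or broadcastable
    to the batch shape.  Input enters the voltage equation additively and
    linearly (scaled by 1/C for Hodgkin-Huxley).
    """
    state = np.asarray(state, dtype=float)
    if state.shape[-1] != spec.state_dim:
        raise ValueError(f"state must have trailing dim {spec.state_dim}")
    if not np.all(np.isfinite(state)):
        raise FloatingPointError("non-finite state passed to drift (numerical blow-up?)")
    return _DRIFT_DISPATCH[spec.model_id](spec.params, state, np.asarray(I, dtype=float))


def observable(spec: ModelSpec, state):
    """Residual nonlinearity r(state): voltage drift minus linear part and input.

    The long-run temporal average of this quantity under constant input
    defines the effective nonlinearity S.
    """
    state = np.asarray(state, dtype=float)
    return _OBSERVABLE_DISPATCH[spec.model_id](spec.params, state)


def noise_amplitudes(spec: ModelSpec) -> np.ndarray:
    """Per-coordinate white-noise amplitudes (voltage first)."""
    g = np.zeros(spec.state_dim)
    g[spec.voltage_index] = spec.noise_V
    aux_idx = [i for i in range(spec.state_dim) if i != spec.voltage_index]
    g[aux_idx] = spec.noise_aux
    return g


def fixed_point(spec: ModelSpec, I: float, guess: Sequence[float] | None = None,
                tol: float = 1e-10) -> np.ndarray:
    """Equilibrium of the deterministic single neuron at constant input I.

    Root-finding on the drift from ``guess``; raises ``FixedPointError`` on
    non-convergence so callers can retry from a different guess.
    """
    from scipy.optimize import root

    if guess is None:
        guess = _default_guess(spec)
    guess = np.asarray(guess, dtype=float)
    if not np.all(np.isfinite(guess)):
        raise ValueError("guess must be finite")
    sol = root(lambda s: drift(spec, s, I), guess, method="hybr", tol=1e-13)
    resid = np.max(np.abs(drift(spec, sol.x, I)))
    if resid > tol:
        raise FixedPointError(
            f"fixed_point did not converge for {spec.model_id} at I={I}: "
            f"max|drift|={resid:.3e}")
    return sol.x


def _default_guess(spec: ModelSpec) -> np.ndarray:
    if spec.model_id == "hh":
        V = 0.0
        return np.concatenate([[V], hh_gating_steady_state(spec.params, V)])
    if spec.model_id == "mckean":
        return np.array([spec.params.v_lo - 0.5, (spec.params.v_lo - 0.5) / spec.params.b])
    if spec.model_id == "fhn":
        return np.array([-1.2, -0.6])
    return np.zeros(spec.state_dim)


def hh_gating_steady_state(p: HHParams, V) -> np.ndarray:
    """Voltage-clamped gating steady state x_inf(V) = alpha / (alpha + beta)."""
    V = np.asarray(V, dtype=float)
    m = p.alpha_m(V) / (p.alpha_m(V) + p.beta_m(V))
    h = p.alpha_h(V) / (p.alpha_h(V) + p.beta_h(V))
    n = p.alpha_n(V) / (p.alpha_n(V) + p.beta_n(V))
    return np.stack([m, h, n], axis=-1) if V.ndim else np.array([m, h, n])


def linear_part(spec: ModelSpec) -> LinearPart:
    """Linear part L of the model's voltage dynamics (see module docstring)."""
    try:
        builder = _LINEAR_DISPATCH[spec.model_id]
    except KeyError:
        raise ValueError(f"no linear part defined for model {spec.model_id!r}")
    return builder(spec.params)


# --------------------------------------------------------------------------
# registry / serialization
# --------------------------------------------------------------------------

def build_model(model_id: str, noise_V: float = 0.0,
                noise_aux: Sequence[float] = (), **param_overrides) -> ModelSpec:
    """Build a ModelSpec from a registered model id and parameter overrides."""
    if model_id not in _PARAM_TYPES:
        raise ValueError(f"unknown model_id {model_id!r}; known: {sorted(_PARAM_TYPES)}")
    params = _PARAM_TYPES[model_id](**param_overrides)
    return ModelSpec(model_id=model_id, params=params, noise_V=noise_V,
                     noise_aux=tuple(noise_aux))


MODEL_REGISTRY = {mid: (lambda mid=mid, **kw: build_model(mid, **kw))
                  for mid in _PARAM_TYPES}


def spec_to_dict(spec: ModelSpec) -> dict:
    numeric = {k: v for k, v in asdict(spec.params).items()
               if isinstance(v, (int, float)) and v is not None}
    if spec.model_id == "fhn" and spec.params.k is None:
        numeric.pop("k", None)
    return {
        "model_id": spec.model_id,
        "noise_V": float(spec.noise_V),
        "noise_aux": list(spec.noise_aux),
        "params": numeric,
    }


def spec_from_dict(d: dict) -> ModelSpec:
    return build_model(d["model_id"], noise_V=d.get("noise_V", 0.0),
                       noise_aux=d.get("noise_aux", ()), **d.get("params", {}))


def spec_to_yaml(spec: ModelSpec) -> str:
    return yaml.safe_dump(spec_to_dict(spec), sort_keys=True)


def spec_from_yaml(text: str) -> ModelSpec:
    return spec_from_dict(yaml.safe_load(text))
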