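"""Finite stochastic network simulation.

Simulates P populations of N_alpha neurons each.  Every neuron follows its
intrinsic stochastic dynamics (Euler-Maruyama) and receives, on top of its
external input, the synaptically filtered voltages of all its presynaptic
neurons::

    dX_i = [ drift(X_i, I_alpha(t) + offset_i + sum_j J_ij s_j(t)) ] dt
           + g dW_i
    ds_j = (V_j - s_j) / tau_s dt

i.e. the synaptic interaction is the convolution of the presynaptic
membrane potential with the unit-area exponential kernel
eta(t) = exp(-t/tau_s) / tau_s (a constant presynaptic voltage passes
through with unit gain).

Synaptic weights are Gaussian with block structure: a weight from
population beta to population alpha is N(J_mean[a,b] / N_b**mean_exp,
J_disorder[a,b] / N_b**std_exp); the default exponents (1, 1/2) make the
summed input mean independent of N with finite disorder variance.

Randomness is split into named streams (weights, initial conditions,
dynamical noise, input offsets) derived from a single seed, so that e.g.
the connectivity can be held fixed while the dynamical noise varies.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence, Tuple

import numpy as np

from .neuron_models import (
    ModelSpec, drift, fixed_point, noise_amplitudes, FixedPointError,
    spec_to_dict, spec_from_dict,
)

__all__ = [
    "NetworkConfig",
    "WeightMatrix",
    "NetworkTrajectory",
    "BlowUpError",
    "substream",
    "sample_weights",
    "simulate_network",
    "population_average",
    "save_trajectory",
    "load_trajectory",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible RNG stream derived from a base seed."""
    key = zlib.crc32(name.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


class BlowUpError(RuntimeError):
    """Non-finite state encountered during integration."""

    def __init__(self, t: float):
        super().__init__(
            f"state became non-finite at t={t:.6g} ms; consider a smaller dt")
        self.t = t


def _as_input_fn(inputs, P: int) -> Callable[[float], np.ndarray]:
    if inputs is None:
        zero = np.zeros(P)
        return lambda t: zero
    if callable(inputs):
        return lambda t: np.broadcast_to(np.asarray(inputs(t), dtype=float), (P,))
    if isinstance(inputs, (list, tuple)) and all(callable(f) for f in inputs):
        fns = list(inputs)
        if len(fns) != P:
            raise ValueError("need one input function per population")
        return lambda t: np.array([f(t) for f in fns], dtype=float)
    const = np.broadcast_to(np.asarray(inputs, dtype=float), (P,)).copy()
    return lambda t: const


@dataclass
class NetworkConfig:
    """Configuration of a P-population stochastic network."""

    spec: ModelSpec
    P: int = 1
    N: Tuple[int, ...] = (100,)
    J_mean: np.ndarray = None          # (P, P), receiver row, sender column
    J_disorder: np.ndarray = None      # (P, P), >= 0
    tau_s: float = 15.0                # synaptic time constant, ms
    inputs: object = None              # callable t -> (P,), per-pop callables, or const
    input_heterogeneity: float = 0.0   # lambda: std of per-neuron constant offsets
    dt: float = 0.05
    T_total: float = 500.0
    seed: int = 0
    init_jitter: float = 0.02
    init_state: Optional[np.ndarray] = None   # (N_tot, dim) override
    mean_exp: float = 1.0
    std_exp: float = 0.5
    record_stride: int = 1
    store_aux: bool = True
    frozen_voltage: Optional[float] = None    # test mode: hold all V at a constant

    def __post_init__(self):
        self.N = tuple(int(n) for n in np.atleast_1d(self.N))
        if len(self.N) == 1 and self.P > 1:
            self.N = self.N * self.P
        if len(self.N) != self.P or any(n < 1 for n in self.N):
            raise ValueError("need one N >= 1 per population")
        self.J_mean = (np.zeros((self.P, self.P)) if self.J_mean is None
                       else np.array(self.J_mean, dtype=float).reshape(self.P, self.P))
        self.J_disorder = (np.zeros((self.P, self.P)) if self.J_disorder is None
                           else np.array(self.J_disorder, dtype=float).reshape(self.P, self.P))
        if np.any(self.J_disorder < 0):
            raise ValueError("J_disorder entries must be >= 0")
        if self.tau_s <= 0 or self.dt <= 0 or self.T_total <= 0:
            raise ValueError("tau_s, dt, T_total must be positive")
        if self.input_heterogeneity < 0:
            raise ValueError("input_heterogeneity must be >= 0")

    @property
    def N_total(self) -> int:
        return sum(self.N)

    @property
    def population_index(self) -> np.ndarray:
        return np.repeat(np.arange(self.P), self.N)

    def input_fn(self) -> Callable[[float], np.ndarray]:
        return _as_input_fn(self.inputs, self.P)


@dataclass
class WeightMatrix:
    """Dense block-structured synaptic weight matrix (receiver x sender)."""

    J: np.ndarray
    config: NetworkConfig

    def block(self, a: int, b: int) -> np.ndarray:
        off = np.concatenate([[0], np.cumsum(self.config.N)])
        return self.J[off[a]:off[a + 1], off[b]:off[b + 1]]


@dataclass
class NetworkTrajectory:
    """Recorded realization of the network dynamics."""

    time: np.ndarray                 # (n_rec,)
    V: np.ndarray                    # (N_tot, n_rec)
    aux: Optional[np.ndarray]        # (N_tot, dim-1, n_rec) or None
    syn: np.ndarray                  # (N_tot, n_rec) synaptic filter states
    population_index: np.ndarray     # (N_tot,)
    seed: int
    dt: float                        # recording step (config dt * stride)
    spec: Optional[ModelSpec] = None

    def __post_init__(self):
        steps = np.diff(self.time)
        if steps.size and not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ValueError("time grid must be uniform")


def sample_weights(config: NetworkConfig, rng: Optional[np.random.Generator] = None
                   ) -> WeightMatrix:
    """Draw the Gaussian block-structured weight matrix.

    Entry J_ij for i in population a, j in population b is drawn
    independently N(J_mean[a,b]/N_b**mean_exp, J_disorder[a,b]/N_b**std_exp).
    """
    if rng is None:
        rng = substream(config.seed, "weights")
    Ntot = config.N_total
    J = np.empty((Ntot, Ntot))
    off = np.concatenate([[0], np.cumsum(config.N)])
    for a in range(config.P):
        for b in range(config.P):
            mu = config.J_mean[a, b] / config.N[b] ** config.mean_exp
            sd = config.J_disorder[a, b] / config.N[b] ** config.std_exp
            blk = rng.standard_normal((config.N[a], config.N[b])) * sd + mu
            J[off[a]:off[a + 1], off[b]:off[b + 1]] = blk
    return WeightMatrix(J=J, config=config)


def _default_initial_state(config: NetworkConfig, rng: np.random.Generator) -> np.ndarray:
    """Deterministic fixed point at the t=0 input, plus small Gaussian jitter."""
    spec = config.spec
    I0 = config.input_fn()(0.0)
    dim = spec.state_dim
    X = np.zeros((config.N_total, dim))
    pop = config.population_index
    for a in range(config.P):
        try:
            fp = fixed_point(spec, float(I0[a]))
        except FixedPointError:
            from .neuron_models import _default_guess
            fp = _default_guess(spec)
        X[pop == a] = fp
    X += config.init_jitter * rng.standard_normal(X.shape)
    if spec.model_id == "hh":
        X[:, 1:] = np.clip(X[:, 1:], 0.0, 1.0)
    return X


def simulate_network(config: NetworkConfig,
                     weights: Optional[WeightMatrix] = None) -> NetworkTrajectory:
    """Euler-Maruyama integration of the full network."""
    spec = config.spec
    dim = spec.state_dim
    Ntot = config.N_total
    pop = config.population_index

    if weights is None:
        weights = sample_weights(config)
    J = weights.J
    if J.shape != (Ntot, Ntot):
        raise ValueError("weight matrix shape inconsistent with config")

    rng_noise = substream(config.seed, "noise")
    rng_init = substream(config.seed, "init")
    rng_off = substream(config.seed, "offsets")

    if config.init_state is not None:
        X = np.array(config.init_state, dtype=float)
        if X.shape != (Ntot, dim):
            raise ValueError("init_state must have shape (N_total, state_dim)")
    else:
        X = _default_initial_state(config, rng_init)

    offsets = (config.input_heterogeneity * rng_off.standard_normal(Ntot)
               if config.input_heterogeneity > 0 else np.zeros(Ntot))

    input_fn = config.input_fn()
    g = noise_amplitudes(spec)
    noisy = np.nonzero(g > 0)[0]
    sqdt = np.sqrt(config.dt)
    is_hh = spec.model_id == "hh"
    frozen = config.frozen_voltage

    s = X[:, spec.voltage_index].copy()          # synaptic filter state
    if frozen is not None:
        # test mode: voltages are clamped after the filter is initialized
        # from the (possibly zero) init_state, so the filter step response
        # toward the clamped value is observable.
        X[:, spec.voltage_index] = frozen
    nsteps = int(round(config.T_total / config.dt))
    stride = max(1, int(config.record_stride))
    rec_idx = np.arange(0, nsteps + 1, stride)
    n_rec = len(rec_idx)

    V_store = np.empty((Ntot, n_rec), dtype=np.float32)
    syn_store = np.empty((Ntot, n_rec), dtype=np.float32)
    aux_store = (np.empty((Ntot, dim - 1, n_rec), dtype=np.float32)
                 if config.store_aux else None)
    aux_cols = [i for i in range(dim) if i != spec.voltage_index]

    def record(k_rec):
        V_store[:, k_rec] = X[:, spec.voltage_index]
        syn_store[:, k_rec] = s
        if aux_store is not None:
            aux_store[:, :, k_rec] = X[:, aux_cols]

    record(0)
    k_rec = 1
    dt = config.dt
    for k in range(nsteps):
        t = k * dt
        if frozen is None:
            with np.errstate(over="ignore", invalid="ignore"):
                I_tot = input_fn(t)[pop] + offsets + J @ s
                try:
                    dX = drift(spec, X, I_tot)
                except FloatingPointError as e:
                    raise BlowUpError(t) from e
                X += dt * dX
            for j in noisy:
                X[:, j] += sqdt * g[j] * rng_noise.standard_normal(Ntot)
            if is_hh:
                np.clip(X[:, 1:], 0.0, 1.0, out=X[:, 1:])
        s += dt * (X[:, spec.voltage_index] - s) / config.tau_s
        if (k + 1) % 200 == 0 and not np.all(np.isfinite(X[:, spec.voltage_index])):
            raise BlowUpError((k + 1) * dt)
        if (k + 1) % stride == 0 and k_rec < n_rec:
            record(k_rec)
            k_rec += 1

    if not np.all(np.isfinite(X)):
        raise BlowUpError(nsteps * dt)

    return NetworkTrajectory(
        time=rec_idx * dt,
        V=V_store,
        aux=aux_store,
        syn=syn_store,
        population_index=pop,
        seed=config.seed,
        dt=dt * stride,
        spec=spec,
    )


def population_average(traj: NetworkTrajectory, alpha: int) -> np.ndarray:
    """Arithmetic mean of member voltages at each recorded time point."""
    mask = traj.population_index == alpha
    if not mask.any():
        raise ValueError(f"no neurons in population {alpha}")
    return traj.V[mask].mean(axis=0, dtype=np.float64)


# --------------------------------------------------------------------------
# storage
# --------------------------------------------------------------------------

def save_trajectory(path: str, traj: NetworkTrajectory) -> None:
    """Store a trajectory as HDF5 (.h5/.hdf5) or NPZ (anything else)."""
    spec_d = spec_to_dict(traj.spec) if traj.spec is not None else None
    if str(path).endswith((".h5", ".hdf5")):
        import h5py
        import json
        with h5py.File(path, "w") as f:
            f.create_dataset("time", data=traj.time)
            f.create_dataset("V", data=traj.V)
            if traj.aux is not None:
                f.create_dataset("aux", data=traj.aux)
            f.create_dataset("syn", data=traj.syn)
            f.create_dataset("population_index", data=traj.population_index)
            f.attrs["seed"] = traj.seed
            f.attrs["dt"] = traj.dt
            if spec_d is not None:
                f.attrs["spec"] = json.dumps(spec_d)
    else:
        import json
        np.savez_compressed(
            path, time=traj.time, V=traj.V, syn=traj.syn,
            population_index=traj.population_index,
            aux=traj.aux if traj.aux is not None else np.empty(0),
            seed=traj.seed, dt=traj.dt,
            spec=json.dumps(spec_d) if spec_d is not None else "")


def load_trajectory(path: str) -> NetworkTrajectory:
    import json
    if str(path).endswith((".h5", ".hdf5")):
        import h5py
        with h5py.File(path, "r") as f:
            spec = (spec_from_dict(json.loads(f.attrs["spec"]))
                    if "spec" in f.attrs else None)
            return NetworkTrajectory(
                time=f["time"][:], V=f["V"][:],
                aux=f["aux"][:] if "aux" in f else None,
                syn=f["syn"][:], population_index=f["population_index"][:],
                seed=int(f.attrs["seed"]), dt=float(f.attrs["dt"]), spec=spec)
    d = np.load(path, allow_pickle=False)
    aux = d["aux"] if d["aux"].size else None
    spec = spec_from_dict(json.loads(str(d["spec"]))) if str(d["spec"]) else None
    return NetworkTrajectory(
        time=d["time"], V=d["V"], aux=aux, syn=d["syn"],
        population_index=d["population_index"], seed=int(d["seed"]),
        dt=float(d["dt"]), spec=spec)
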