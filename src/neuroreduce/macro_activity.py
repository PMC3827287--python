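"""Macroscopic activity: windowed population-averaged voltage.

The macroscopic activity nu_alpha(t) of a population is the empirical
average of member voltages convolved with a normalized symmetric time
window.  The window width must exceed the duration of a spike (so the
stereotyped impulses are averaged out) while remaining small relative to
the timescale of the inputs.  Samples within half a window of either edge
are flagged as transient: there the symmetric convolution is imprecise and
downstream comparisons exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .network_sim import NetworkTrajectory, population_average

__all__ = ["WindowSpec", "MacroTrajectory", "apply_window", "network_macro",
           "macro_to_csv", "macro_to_hdf5", "macro_from_hdf5",
           "macro_from_arrays"]

_SHAPES = ("rectangular", "triangular", "gaussian-truncated")


@dataclass(frozen=True)
class WindowSpec:
    """Normalized symmetric averaging window on a uniform time grid."""

    width: float              # T_w, ms
    dt: float                 # grid step the kernel is sampled on, ms
    shape: str = "rectangular"
    kernel: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if self.shape not in _SHAPES:
            raise ValueError(f"shape must be one of {_SHAPES}")
        if self.width <= 0 or self.dt <= 0:
            raise ValueError("width and dt must be positive")
        n = int(round(self.width / self.dt))
        n = max(1, n)
        if n % 2 == 0:
            n += 1  # odd length => exactly symmetric about its center
        if self.shape == "rectangular":
            k = np.ones(n)
        elif self.shape == "triangular":
            k = np.bartlett(n + 2)[1:-1]
        else:
            half = (n - 1) / 2.0
            x = np.arange(n) - half
            sd = max(half / 3.0, 1e-12)
            k = np.exp(-0.5 * (x / sd) ** 2)
        k = k / k.sum()
        object.__setattr__(self, "kernel", k)

    @property
    def half_width_samples(self) -> int:
        return (len(self.kernel) - 1) // 2

    def transient_mask(self, n_samples: int) -> np.ndarray:
        """Boolean mask flagging the first and last half-window as transient."""
        mask = np.zeros(n_samples, dtype=bool)
        h = self.half_width_samples
        if h > 0:
            mask[:h] = True
            mask[n_samples - h:] = True
        return mask


@dataclass
class MacroTrajectory:
    """Per-population macroscopic activity time series."""

    time: np.ndarray           # (n,)
    nu: np.ndarray             # (P, n)
    provenance: str = "network-derived"   # or "reduced-model"
    transient_mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.nu = np.atleast_2d(np.asarray(self.nu, dtype=float))
        if self.nu.shape[1] != len(self.time):
            raise ValueError("nu and time length mismatch")
        if not np.all(np.isfinite(self.nu)):
            raise ValueError("macroscopic activity contains non-finite values")
        steps = np.diff(self.time)
        if steps.size and not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ValueError("time grid must be uniform")
        if self.transient_mask is None:
            self.transient_mask = np.zeros(len(self.time), dtype=bool)

    @property
    def P(self) -> int:
        return self.nu.shape[0]


def apply_window(series: np.ndarray, window: WindowSpec) -> np.ndarray:
    """Discrete convolution with the window kernel, reflection-padded edges.

    The output has the same length as the input; the first and last
    half-window samples (``window.transient_mask``) are computed but should
    be treated as transient.
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    h = window.half_width_samples
    if len(window.kernel) > n:
        raise ValueError("window longer than series")
    if h == 0:
        return series.copy()
    padded = np.concatenate([series[h:0:-1], series, series[-2:-h - 2:-1]])
    return np.convolve(padded, window.kernel, mode="valid")


def network_macro(traj: NetworkTrajectory, window: WindowSpec) -> MacroTrajectory:
    """Population-average each population's voltages, then window them."""
    P = int(traj.population_index.max()) + 1
    nu = np.empty((P, len(traj.time)))
    for a in range(P):
        nu[a] = apply_window(population_average(traj, a), window)
    return MacroTrajectory(time=traj.time.copy(), nu=nu,
                           provenance="network-derived",
                           transient_mask=window.transient_mask(len(traj.time)))


def macro_to_csv(macro: MacroTrajectory, path: str) -> None:
    import pandas as pd
    cols = {"time": macro.time}
    for a in range(macro.P):
        cols[f"nu_{a + 1}"] = macro.nu[a]
    cols["transient"] = macro.transient_mask.astype(int)
    pd.DataFrame(cols).to_csv(path, index=False)


def macro_to_hdf5(macro: MacroTrajectory, path: str) -> None:
    import h5py
    with h5py.File(path, "w") as f:
        f.create_dataset("time", data=macro.time)
        f.create_dataset("nu", data=macro.nu)
        f.create_dataset("transient_mask", data=macro.transient_mask)
        f.attrs["provenance"] = macro.provenance


def macro_from_hdf5(path: str) -> MacroTrajectory:
    import h5py
    with h5py.File(path, "r") as f:
        return MacroTrajectory(time=f["time"][:], nu=f["nu"][:],
                               provenance=str(f.attrs["provenance"]),
                               transient_mask=f["transient_mask"][:].astype(bool))


def macro_from_arrays(time, nu, provenance="reduced-model",
                      transient_mask=None) -> MacroTrajectory:
    return MacroTrajectory(time=np.asarray(time, float), nu=nu,
                           provenance=provenance, transient_mask=transient_mask)
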