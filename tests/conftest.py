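import numpy as np
import pytest

from neuroreduce import (
    build_model, EstimateSettings, build_surface, deterministic_sweep,
    mckean_oscillatory_window,
)
from neuroreduce.effective_nonlinearity import _simulate_batch, measure_period


@pytest.fixture(scope="session")
def mckean_spec():
    return build_model("mckean")


@pytest.fixture(scope="session")
def fhn_spec():
    return build_model("fhn")


@pytest.fixture(scope="session")
def hh_spec():
    return build_model("hh")


@pytest.fixture(scope="session")
def hh_branch_system(hh_spec):
    """Deterministic hysteresis sweep of the Hodgkin-Huxley neuron."""
    return deterministic_sweep(hh_spec, np.linspace(0.0, 15.0, 31))


@pytest.fixture(scope="session")
def hh_surface(hh_spec):
    """HH effective-nonlinearity surface at low / moderate / high noise."""
    return build_surface(hh_spec, np.linspace(2.0, 14.0, 13),
                         [0.1, 1.0, 5.0], n_inits=8, seed=0)


@pytest.fixture(scope="session")
def mckean_noise_surface(mckean_spec):
    return build_surface(mckean_spec, np.linspace(-5.0, 5.0, 11),
                         [0.0, 0.3, 1.0], n_inits=4, seed=0)


@pytest.fixture(scope="session")
def mckean_small_eps():
    """Slow-fast McKean reference runs: strongly separated timescales.

    Constant-input temporal averages and measured cycle periods on a grid
    spanning the oscillatory window, used against the closed-form sigmoid
    and transit times (exact in the singular limit).
    """
    spec = build_model("mckean", eps=0.02, c=0.04)
    p = spec.params
    lo, hi = mckean_oscillatory_window(p)
    width = hi - lo
    fracs = np.linspace(0.08, 0.92, 11)
    I_inside = lo + fracs * width
    I_outside = np.array([lo - 0.3 * width, hi + 0.3 * width])
    I_all = np.concatenate([I_inside, I_outside])
    settings = EstimateSettings(dt=0.002, t_transient=400.0, t_average=900.0)
    inits = np.tile([2.0, 0.0], (len(I_all), 1))
    mean, se, traces, trace_dt, vbar, _ = _simulate_batch(
        spec, I_all, 0.0, inits, settings, None)
    periods = [measure_period(traces[i], trace_dt) for i in range(len(I_all))]
    return dict(spec=spec, params=p, window=(lo, hi), I_inside=I_inside,
                I_outside=I_outside, I_all=I_all, values=mean,
                periods=periods, settings=settings)
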