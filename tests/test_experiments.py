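import numpy as np
import pytest

from neuroreduce import (
    build_model, generate_inputs, comparison_metrics, compare_model,
    robustness_sweep, bifurcation_report, mckean_oscillatory_window,
)
from neuroreduce.macro_activity import MacroTrajectory


# --------------------------------------------------------------------------
# synthetic inputs
# --------------------------------------------------------------------------

def test_inputs_time_compression_exact():
    b1 = generate_inputs(3, kappa=1.0, seed=5)
    b2 = generate_inputs(3, kappa=2.0, seed=5)
    for t in (0.0, 123.4, 800.0):
        np.testing.assert_allclose(b2(t), b1(2.0 * t), atol=1e-12)


def test_inputs_gain_zero_is_constant_offset():
    b = generate_inputs(2, gain=0.0, offset=1.25, seed=0)
    for t in (0.0, 50.0, 999.0):
        np.testing.assert_allclose(b(t), 1.25, atol=1e-15)


def test_inputs_seed_reproducible_and_distinct():
    a = generate_inputs(2, seed=3)
    b = generate_inputs(2, seed=3)
    c = generate_inputs(2, seed=4)
    ts = np.linspace(0, 2000, 50)
    va = np.array([a(t) for t in ts])
    np.testing.assert_array_equal(va, np.array([b(t) for t in ts]))
    assert not np.allclose(va, np.array([c(t) for t in ts]))


def test_inputs_bounded():
    b = generate_inputs(4, gain=2.0, offset=0.5, seed=9)
    ts = np.linspace(-500, 5000, 400)
    vals = np.array([b(t) for t in ts])
    assert vals.min() >= 0.5 - 2.0 - 1e-9
    assert vals.max() <= 0.5 + 2.0 + 1e-9


def test_inputs_slower_at_smaller_kappa():
    ts = np.linspace(0, 2000, 2000)
    for kappa_fast, kappa_slow in [(2.0, 1.0), (1.0, 0.5)]:
        fast = generate_inputs(1, kappa=kappa_fast, seed=2)
        slow = generate_inputs(1, kappa=kappa_slow, seed=2)
        d_fast = np.abs(np.diff([fast(t)[0] for t in ts])).max()
        d_slow = np.abs(np.diff([slow(t)[0] for t in ts])).max()
        assert d_slow < d_fast


# --------------------------------------------------------------------------
# comparison metric
# --------------------------------------------------------------------------

def make_pair(seed=0, n=500):
    rng = np.random.default_rng(seed)
    t = np.arange(n) * 1.0
    a = np.cumsum(rng.standard_normal((2, n)), axis=1) * 0.05
    b = a + 0.1 * rng.standard_normal((2, n))
    mask = np.zeros(n, dtype=bool)
    mask[:20] = mask[-20:] = True
    net = MacroTrajectory(time=t, nu=a, transient_mask=mask)
    red = MacroTrajectory(time=t, nu=b, provenance="reduced-model")
    return net, red


def test_metric_shift_invariance_and_scaling():
    net, red = make_pair()
    mad0, rng0, rel0 = comparison_metrics(net, red)
    shift_net, shift_red = make_pair()
    shift_net.nu += 5.0
    shift_red.nu += 5.0
    mad1, rng1, _ = comparison_metrics(shift_net, shift_red)
    np.testing.assert_allclose(mad1, mad0, atol=1e-12)
    scale_net, scale_red = make_pair()
    scale_net.nu *= 3.0
    scale_red.nu *= 3.0
    mad3, _, rel3 = comparison_metrics(scale_net, scale_red)
    np.testing.assert_allclose(mad3, 3 * mad0, atol=1e-12)
    np.testing.assert_allclose(rel3, rel0, atol=1e-12)


def test_metric_excludes_transients():
    net, red = make_pair()
    # corrupt only the transient span: the metric must not change
    mad0, _, _ = comparison_metrics(net, red)
    net.nu[:, :20] += 100.0
    mad1, _, _ = comparison_metrics(net, red)
    np.testing.assert_allclose(mad1, mad0, atol=1e-12)


def test_metric_errors_nonnegative_and_zero_for_identical():
    net, _ = make_pair()
    red = MacroTrajectory(time=net.time.copy(), nu=net.nu.copy(),
                          provenance="reduced-model")
    mad, rng, rel = comparison_metrics(net, red)
    np.testing.assert_allclose(mad, 0.0, atol=1e-15)
    assert np.all(rel >= 0)


# --------------------------------------------------------------------------
# packaged experiments (scaled down for test time)
# --------------------------------------------------------------------------

# scaled down via population size only: shrinking T_total would also shorten
# the generated input ramps and change the experiment's timescale hierarchy
SMALL = dict(N=100)


def test_sweep_single_value_reproduces_comparison():
    tab = robustness_sweep("tau_s", [15.0], model_id="mckean", seeds=(0,), **SMALL)
    res = compare_model("mckean", seed=0, tau_s=15.0, **SMALL)
    assert len(tab) == 3
    np.testing.assert_allclose(np.sort(tab.relative_error.to_numpy()),
                               np.sort(res.relative_error), atol=1e-9)


def test_sweep_records_failures_and_continues():
    tab = robustness_sweep("sigma", [-1.0, 0.2], model_id="mckean",
                           seeds=(0,), **SMALL)
    bad = tab[tab.value == -1.0]
    good = tab[tab.value == 0.2]
    assert bad.error.notna().all()
    assert good.error.isna().all()
    assert len(good) == 3


def test_sweep_unknown_parameter_rejected():
    with pytest.raises(ValueError):
        robustness_sweep("gamma", [1.0])


def test_seed_robustness_of_comparison():
    r0 = compare_model("mckean", seed=0, **SMALL)
    r1 = compare_model("mckean", seed=1, **SMALL)
    # two network realizations give errors within the finite-size scale
    assert np.all(np.abs(r0.relative_error - r1.relative_error) < 0.05)


# --------------------------------------------------------------------------
# bifurcation reports
# --------------------------------------------------------------------------

def test_bifurcation_report_mckean_class1(mckean_spec):
    lo, hi = mckean_oscillatory_window(mckean_spec.params)
    table, info = bifurcation_report(mckean_spec,
                                     np.linspace(lo - 1.5, hi + 1.5, 25))
    assert not info["bistable"]
    assert info["excitability_class"] == "I"
    assert {"I", "direction", "value", "period", "frequency"} <= set(table.columns)


def test_bifurcation_report_hh_class2(hh_spec, hh_branch_system):
    table, info = bifurcation_report(hh_spec, np.linspace(0, 15, 31),
                                     branch_system=hh_branch_system)
    assert info["bistable"]
    assert info["excitability_class"] == "II"
    assert info["onset_frequency"] > 10.0


def test_bifurcation_report_fhn_narrow_window(fhn_spec):
    table, info = bifurcation_report(fhn_spec, np.linspace(-0.2, 1.8, 41),
                                     classify=False)
    if info["bistable"]:
        lo, hi = info["bistable_window"]
        assert hi - lo <= 0.2
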