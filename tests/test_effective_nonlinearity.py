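import json

import numpy as np
import pytest

from neuroreduce import (
    build_model, EstimateSettings, estimate_point, build_surface,
    deterministic_sweep, surface_lookup, split_branches, measure_period,
    mckean_oscillatory_window, mckean_transit_times, mckean_sigmoid,
    mckean_branch_levels, OutsideOscillatoryWindow, TooManyBranchesError,
    HullError, surface_to_json, surface_from_json, surface_to_csv,
    fixed_point,
)
from neuroreduce.neuron_models import McKeanParams, observable
from neuroreduce.effective_nonlinearity import NonlinearitySurface


# --------------------------------------------------------------------------
# analytic path
# --------------------------------------------------------------------------

def test_transit_times_symmetric_at_window_center(mckean_spec):
    p = mckean_spec.params
    lo, hi = mckean_oscillatory_window(p)
    Tm, Tp = mckean_transit_times(0.5 * (lo + hi), p)
    assert Tm == pytest.approx(Tp, rel=1e-12)
    assert Tm > 0


def test_transit_times_outside_window_rejected(mckean_spec):
    p = mckean_spec.params
    lo, hi = mckean_oscillatory_window(p)
    for I in (lo - 0.5, hi + 0.5, lo, hi):
        with pytest.raises(OutsideOscillatoryWindow):
            mckean_transit_times(I, p)


def test_sigmoid_saturates_at_branch_levels(mckean_spec):
    p = mckean_spec.params
    r_minus, r_plus = mckean_branch_levels(p)
    assert mckean_sigmoid(-1e6, p) == r_minus
    assert mckean_sigmoid(+1e6, p) == r_plus
    lo, hi = mckean_oscillatory_window(p)
    assert mckean_sigmoid(lo - 1e-9, p) == r_minus   # constant fixed-point branch


def test_sigmoid_continuous_and_nondecreasing(mckean_spec):
    p = mckean_spec.params
    lo, hi = mckean_oscillatory_window(p)
    I = np.linspace(lo - 1.0, hi + 1.0, 2001)
    S = mckean_sigmoid(I, p)
    assert np.all(np.diff(S) >= -1e-12)
    # approach to the left threshold from inside is monotone (logarithmic)
    deltas = (hi - lo) * np.array([1e-3, 1e-5, 1e-7, 1e-9])
    vals = np.array([mckean_sigmoid(lo + d, p) for d in deltas])
    r_minus, _ = mckean_branch_levels(p)
    assert np.all(np.diff(vals) < 0)        # shrinking toward the branch level
    assert abs(vals[-1] - r_minus) < 0.1 * (mckean_branch_levels(p)[1] - r_minus)


def test_sigmoid_vertical_tangent_at_thresholds(mckean_spec):
    p = mckean_spec.params
    lo, hi = mckean_oscillatory_window(p)
    h = (hi - lo) * 1e-4
    slope_in = (mckean_sigmoid(lo + 2 * h, p) - mckean_sigmoid(lo + h, p)) / h
    slope_out = (mckean_sigmoid(lo - h, p) - mckean_sigmoid(lo - 2 * h, p)) / h
    assert slope_in > 10 * max(slope_out, 1e-12)
    assert slope_in > 0


def test_period_grows_approaching_onset(mckean_spec):
    """Arbitrarily slow orbits near onset (class I signature), closed form."""
    p = mckean_spec.params
    lo, hi = mckean_oscillatory_window(p)
    dists = (hi - lo) * np.array([0.2, 0.1, 0.05, 0.02, 0.01, 0.005])
    periods = [sum(mckean_transit_times(lo + d, p)) for d in dists]
    assert np.all(np.diff(periods) > 0)


def test_transit_times_match_simulated_period(mckean_small_eps):
    """Closed-form T- + T+ equals the simulated cycle period within 2%."""
    p = mckean_small_eps["params"]
    for I, per in zip(mckean_small_eps["I_inside"],
                      mckean_small_eps["periods"][:len(mckean_small_eps["I_inside"])]):
        Tm, Tp = mckean_transit_times(I, p)
        assert per == pytest.approx(Tm + Tp, rel=0.02)


# --------------------------------------------------------------------------
# numerical estimation
# --------------------------------------------------------------------------

def test_estimate_point_fixed_point_branch(mckean_spec):
    p = mckean_spec.params
    I = -5.0
    est = estimate_point(mckean_spec, I, 0.0, init=fixed_point(mckean_spec, I),
                         settings=EstimateSettings(dt=0.02, t_transient=200.0,
                                                   t_average=400.0))
    r_minus, _ = mckean_branch_levels(p)
    assert abs(est.value - r_minus) < 1e-3
    assert est.period is None
    assert est.stderr < 1e-6


def test_estimate_point_oscillatory_matches_sigmoid():
    spec = build_model("mckean", eps=0.1, c=0.04)
    p = spec.params
    lo, hi = mckean_oscillatory_window(p)
    I = lo + 0.4 * (hi - lo)
    est = estimate_point(spec, I, 0.0, init=[2.0, 0.0],
                         settings=EstimateSettings(dt=0.005, t_transient=300.0,
                                                   t_average=800.0))
    span = mckean_branch_levels(p)[1] - mckean_branch_levels(p)[0]
    assert abs(est.value - mckean_sigmoid(I, p)) < 0.02 * span
    assert est.period is not None


def test_estimate_point_init_independent_within_basin(mckean_spec):
    sett = EstimateSettings(dt=0.02, t_transient=300.0, t_average=500.0)
    a = estimate_point(mckean_spec, -5.0, 0.0, init=[-2.0, -3.0], settings=sett)
    b = estimate_point(mckean_spec, -5.0, 0.0, init=[0.5, 0.5], settings=sett)
    assert abs(a.value - b.value) < 1e-3


def test_estimate_point_short_horizon_warns(mckean_spec):
    est = estimate_point(mckean_spec, 0.0, 0.0, init=[2.0, 0.0],
                         settings=EstimateSettings(dt=0.02, t_transient=200.0,
                                                   t_average=100.0))
    assert est.period is not None
    assert est.warning is not None


def test_measure_period_on_synthetic_signal():
    dt = 0.1
    t = np.arange(6000) * dt
    x = np.sin(2 * np.pi * t / 7.3) + 0.05 * np.random.default_rng(0).standard_normal(len(t))
    assert measure_period(x, dt) == pytest.approx(7.3, rel=0.01)
    assert measure_period(np.ones(1000), dt) is None


# --------------------------------------------------------------------------
# clustering
# --------------------------------------------------------------------------

def test_split_branches_single_cluster_with_jitter():
    vals = 1.0 + 1e-9 * np.arange(6)
    out = split_branches(vals, np.zeros(6), min_separation=0.01)
    assert len(out) == 1


def test_split_branches_two_clusters():
    vals = np.array([0.0, 0.02, -0.01, 1.0, 1.03, 0.98])
    out = split_branches(vals, np.full(6, 0.01), min_separation=0.05)
    assert len(out) == 2
    low, high = out
    assert sorted(vals[low]) == sorted([0.0, 0.02, -0.01])
    assert len(high) == 3


def test_split_branches_three_clusters_error():
    vals = np.array([0.0, 0.01, 5.0, 5.01, 10.0, 10.01])
    with pytest.raises(TooManyBranchesError):
        split_branches(vals, np.full(6, 0.001), min_separation=0.05)


def test_split_branches_respects_stderr():
    # gap comparable to the estimation noise: no split
    vals = np.array([0.0, 0.3, 0.6, 0.9, 1.2, 1.5])
    out = split_branches(vals, np.full(6, 0.5), min_separation=0.01)
    assert len(out) == 1


# --------------------------------------------------------------------------
# surfaces and lookup
# --------------------------------------------------------------------------

def test_surface_regimes_and_window(hh_surface):
    assert hh_surface.regimes[0] == "II"
    assert hh_surface.regimes[-1] == "I"
    win = hh_surface.bistable_window(0.1)
    assert win is not None and win[0] < win[1] or win[0] == win[1]
    assert hh_surface.bistable_window(5.0) is None
    # two-branch points form a contiguous input interval at low noise
    counts = hh_surface.branch_counts[0]
    two = np.nonzero(counts == 2)[0]
    assert np.array_equal(two, np.arange(two[0], two[-1] + 1))


def test_surface_branches_ordered(hh_surface):
    bv = hh_surface.branch_values
    both = hh_surface.branch_counts == 2
    assert np.all(bv[both][:, 0] < bv[both][:, 1])


def test_surface_lookup_grid_nodes_exact(mckean_noise_surface):
    s = mckean_noise_surface
    for k, sig in enumerate(s.sigma_grid):
        for i, I in enumerate(s.I_grid):
            assert surface_lookup(s, I, sig, branch="pooled") == pytest.approx(
                s.pooled[k, i], abs=1e-12)


def test_surface_lookup_midpoint_and_monotone(mckean_noise_surface):
    s = mckean_noise_surface
    I0, I1 = s.I_grid[3], s.I_grid[4]
    mid = surface_lookup(s, 0.5 * (I0 + I1), s.sigma_grid[1], branch="pooled")
    assert mid == pytest.approx(0.5 * (s.pooled[1, 3] + s.pooled[1, 4]), abs=1e-12)
    lo = min(s.pooled[1, 3], s.pooled[1, 4])
    hi = max(s.pooled[1, 3], s.pooled[1, 4])
    assert lo - 1e-12 <= mid <= hi + 1e-12


def test_surface_lookup_hull_errors(mckean_noise_surface):
    s = mckean_noise_surface
    with pytest.raises(HullError):
        surface_lookup(s, s.I_grid[-1] + 1.0, s.sigma_grid[0])
    with pytest.raises(HullError):
        surface_lookup(s, 0.0, s.sigma_grid[-1] + 10.0)


def test_surface_lookup_sigma_modes(mckean_noise_surface):
    s = mckean_noise_surface
    v_near = surface_lookup(s, 0.0, 0.1, branch="pooled", sigma_mode="nearest")
    assert v_near == pytest.approx(surface_lookup(s, 0.0, s.sigma_grid[0],
                                                  branch="pooled"), abs=1e-12)
    v_lin = surface_lookup(s, 0.0, 0.15, branch="pooled", sigma_mode="linear")
    a = surface_lookup(s, 0.0, s.sigma_grid[0], branch="pooled")
    b = surface_lookup(s, 0.0, s.sigma_grid[1], branch="pooled")
    assert min(a, b) - 1e-12 <= v_lin <= max(a, b) + 1e-12


def test_surface_serialization_roundtrip(tmp_path, mckean_noise_surface):
    s = mckean_noise_surface
    back = surface_from_json(surface_to_json(s))
    np.testing.assert_allclose(back.branch_values, s.branch_values)
    np.testing.assert_allclose(back.pooled_voltage, s.pooled_voltage)
    assert back.regimes == s.regimes
    surface_to_csv(s, str(tmp_path / "s.csv"))
    import pandas as pd
    df = pd.read_csv(tmp_path / "s.csv")
    assert set(df.columns) == {"I", "sigma", "branch", "value", "stderr"}
    assert len(df) == int(s.branch_counts.sum())


# --------------------------------------------------------------------------
# deterministic sweeps
# --------------------------------------------------------------------------

def test_mckean_sweep_no_hysteresis(mckean_spec):
    bs = deterministic_sweep(mckean_spec, np.linspace(-5.0, 5.0, 21))
    assert bs.bistable_window is None
    # forward and backward sweeps agree at every input
    by_I = {}
    for pt in bs.points:
        by_I.setdefault(pt.I, []).append(pt.value)
    span = max(p.value for p in bs.points) - min(p.value for p in bs.points)
    for I, vals in by_I.items():
        assert abs(vals[0] - vals[1]) < 0.02 * span


def test_hh_sweep_bistable_window_and_class2(hh_branch_system):
    bs = hh_branch_system
    win = bs.bistable_window
    assert win is not None and win[1] > win[0]
    assert bs.onset_frequency() > 10.0    # oscillations appear at finite frequency


def test_fhn_sweep_narrow_bistable_window(fhn_spec):
    bs = deterministic_sweep(fhn_spec, np.linspace(-0.2, 1.8, 41))
    win = bs.bistable_window
    if win is not None:
        assert win[1] - win[0] <= 0.2
    # the cycle branch exists well inside the spiking range
    assert bs.I_cycle.size > 5


def test_sweep_matches_low_noise_surface(mckean_spec, mckean_noise_surface):
    """Stable-branch values from the hysteresis sweep coincide with the
    sigma -> 0 surface within 2% of the dynamic range."""
    bs = deterministic_sweep(mckean_spec, mckean_noise_surface.I_grid)
    slice0 = mckean_noise_surface.pooled[0]
    span = np.ptp(slice0)
    for I, v in zip(mckean_noise_surface.I_grid, slice0):
        pts = [p.value for p in bs.points if p.I == I and p.settled]
        assert abs(np.mean(pts) - v) < 0.02 * span
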