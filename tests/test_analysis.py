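import numpy as np
import pytest

from cldyn import SimulationConfig, simulate
from cldyn.analysis import (
    ChlorideIndexResult, IOCurve, UndefinedMeasure, chloride_index, half_max,
    ifr, io_curve, mean_rate,
)
from cldyn.calibration import distal_fin_program


class TestMeanRate:
    def test_basic_count(self):
        assert mean_rate(np.array([10, 200, 300, 400, 900.0]), 1000.0) == 5.0

    def test_empty(self):
        assert mean_rate(np.array([]), 1000.0) == 0.0

    def test_window_additivity(self):
        spikes = np.array([50.0, 150, 250, 600, 800, 950])
        first = mean_rate(spikes[spikes < 500], 500.0)
        second = mean_rate(spikes[spikes >= 500], 500.0)
        assert mean_rate(spikes, 1000.0) == pytest.approx((first + second) / 2)

    def test_rejects_bad_window(self):
        with pytest.raises(ValueError):
            mean_rate(np.array([1.0]), 0.0)


class TestIFR:
    def test_printed_formula(self):
        # 3 spikes pooled over K=5 trials in a 20 ms window -> 30 Hz
        trains = [np.array([95.0]), np.array([99.0]), np.array([85.0]),
                  np.array([]), np.array([])]
        assert ifr(trains, 100.0, 20.0) == pytest.approx(30.0)

    def test_no_spikes_zero_everywhere(self):
        trains = [np.array([])] * 5
        out = ifr(trains, [100.0, 500.0, 900.0], 20.0)
        assert np.all(out == 0.0)

    def test_identical_trials_equal_single_trial_rate(self):
        tr = np.array([30.0, 45.0, 90.0])
        assert ifr([tr] * 7, 100.0, 100.0) == pytest.approx(
            ifr([tr], 100.0, 100.0))

    def test_backward_window_semantics(self):
        trains = [np.array([79.9, 80.1, 100.0])]
        # (80, 100] backward window of width 20 at t=100
        assert ifr(trains, 100.0, 20.0) == pytest.approx(2 / 0.020)

    def test_truncated_window_signalled(self):
        with pytest.raises(ValueError, match="truncated"):
            ifr([np.array([5.0])], 10.0, 20.0)

    def test_integrated_ifr_equals_total_count(self):
        rng = np.random.default_rng(0)
        trains = [np.sort(rng.uniform(0, 1000, 40)) for _ in range(5)]
        dt = 20.0
        t_grid = np.arange(dt, 1000.0 + dt / 2, dt)
        total = np.sum(ifr(trains, t_grid, dt)) * dt / 1000.0
        assert total == pytest.approx(sum(len(t) for t in trains) / 5,
                                      rel=1e-9)


def _logistic_curve(x0=10.0, rmax=120.0, k=1.0, grid=None, inhibition=0.0):
    x = np.linspace(0, 30, 121) if grid is None else np.asarray(grid)
    r = rmax / (1 + np.exp(-k * (x - x0)))
    return IOCurve("relative_conductance", x, r, 1, "static", inhibition)


class TestHalfMax:
    def test_logistic_midpoint(self):
        c = _logistic_curve(x0=10.0)
        hm = half_max(c)
        # at the midpoint the logistic attains rmax/2 but its max on a finite
        # grid is slightly below rmax; allow grid resolution
        assert hm.x50 == pytest.approx(10.0, abs=0.3)

    def test_flat_curve_undefined(self):
        c = IOCurve("relative_conductance", [0, 1, 2], [0, 0, 0], 1,
                    "static", 0.0)
        with pytest.raises(UndefinedMeasure):
            half_max(c)

    def test_translation_equivariance(self):
        c = _logistic_curve(x0=10.0)
        shifted = IOCurve("relative_conductance", c.x + 3.5, c.rate_hz, 1,
                          "static", 0.0)
        assert half_max(shifted).x50 == pytest.approx(half_max(c).x50 + 3.5)

    def test_reference_maximum_override(self):
        c = _logistic_curve(x0=10.0, rmax=80.0)
        hm = half_max(c, max_rate_hz=120.0)   # half of the reference is 60
        assert hm.x50 > 10.0                  # later than the curve's own midpoint

    def test_never_reaching_half_signalled(self):
        c = _logistic_curve(rmax=40.0)
        with pytest.raises(UndefinedMeasure):
            half_max(c, max_rate_hz=120.0)


class TestChlorideIndex:
    def test_dynamic_equals_static_gives_zero(self):
        no_inh = _logistic_curve(x0=8.0)
        dyn = _logistic_curve(x0=12.0, inhibition=4.0)
        res = chloride_index(dyn, dyn, no_inh)
        assert res.index == pytest.approx(0.0, abs=1e-12)

    def test_vanishing_dynamic_offset_gives_one(self):
        no_inh = _logistic_curve(x0=8.0)
        dyn = _logistic_curve(x0=8.0, inhibition=4.0)
        stat = _logistic_curve(x0=14.0, inhibition=4.0)
        res = chloride_index(dyn, stat, no_inh)
        assert res.index == pytest.approx(1.0, abs=1e-9)

    def test_direct_triple(self):
        # x50 triple (2, 3, 4) -> a=1, b=2, index=0.5
        no_inh = _logistic_curve(x0=2.0)
        dyn = _logistic_curve(x0=3.0, inhibition=4.0)
        stat = _logistic_curve(x0=4.0, inhibition=4.0)
        res = chloride_index(dyn, stat, no_inh)
        assert res.a == pytest.approx(1.0, abs=0.05)
        assert res.b == pytest.approx(2.0, abs=0.05)
        assert res.index == pytest.approx(0.5, abs=0.03)

    def test_zero_static_offset_undefined(self):
        no_inh = _logistic_curve(x0=8.0)
        with pytest.raises(UndefinedMeasure):
            chloride_index(no_inh, no_inh, no_inh)

    def test_invariant_to_rate_axis_rescaling(self):
        # the index depends only on abscissa offsets
        no_inh = _logistic_curve(x0=6.0)
        dyn = _logistic_curve(x0=9.0, inhibition=4.0)
        stat = _logistic_curve(x0=13.0, inhibition=4.0)
        base = chloride_index(dyn, stat, no_inh).index
        for c in (0.25, 3.0):
            scale = lambda cu: IOCurve(cu.abscissa_kind, cu.x,
                                       c * cu.rate_hz, cu.trials,
                                       cu.chloride_mode, cu.inhibition)
            scaled = chloride_index(scale(dyn), scale(stat),
                                    scale(no_inh)).index
            assert scaled == pytest.approx(base, abs=1e-9)


class TestIOCurveSimulation:
    def test_monotone_without_inhibition(self, tuned_model):
        curve = io_curve(tuned_model, 0.0, "static", (10.0, 20.0, 40.0),
                         trials=1, seed=5, duration_ms=500.0)
        r = curve.rate_hz
        assert r[2] > r[0]
        assert r[1] >= r[0] - 1.0 and r[2] >= r[1] - 1.0

    def test_grid_must_be_sorted(self):
        with pytest.raises(ValueError):
            IOCurve("relative_conductance", [3, 1, 2], [0, 0, 0], 1,
                    "dynamic", 0.0)


def test_distal_inhibition_saturates_under_dynamic_chloride(tuned_model):
    """Adding distal GABA synapses keeps lowering output when chloride is
    static but loses efficacy when chloride is dynamic."""
    rates = {}
    for mode in ("dynamic", "static"):
        for ni in (300, 800):
            stim = distal_fin_program(tuned_model, 250, ni, 20.0, seed=6)
            res = simulate(tuned_model, stim,
                           SimulationConfig(duration_ms=1000.0,
                                            chloride_mode=mode))
            rates[mode, ni] = mean_rate(res.spike_times_ms, 1000.0)
    drop_static = rates["static", 300] - rates["static", 800]
    drop_dynamic = rates["dynamic", 300] - rates["dynamic", 800]
    assert drop_static > drop_dynamic
    assert rates["dynamic", 800] > rates["static", 800]
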