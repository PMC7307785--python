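import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp
from scipy.special import erf

from cldyn import build_default_model, simulate, SimulationConfig
from cldyn.chloride import (
    DiffusionParams, chloride_step, diffusion_exchange, egaba_combine,
    enable_dynamic_potassium, kcc2_equilibrium_cl, nernst,
)
from cldyn.constants import DEFAULT_CONSTANTS
from cldyn.mechanisms import NumericalFailure


class TestNernst:
    def test_chloride_table_value(self):
        assert nernst(-1, 4.25, 135.0) == pytest.approx(-92.42, abs=0.05)

    def test_equal_concentrations(self):
        for z in (-1, 1, 2):
            assert nernst(z, 10.0, 10.0) == 0.0

    def test_potassium_value(self):
        assert nernst(1, 140.0, 4.0) == pytest.approx(-95.01, abs=0.05)

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            nernst(-1, 0.0, 135.0)

    @given(st.floats(0.5, 50.0))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_with_inverse(self, ci):
        e = nernst(-1, ci, 135.0)
        back = 135.0 * math.exp(e / DEFAULT_CONSTANTS.rtf_mV)
        assert back == pytest.approx(ci, rel=1e-10)


class TestEgabaCombine:
    def test_table_values(self):
        assert egaba_combine(-92.42, -17.39) == pytest.approx(-77.41, abs=0.05)

    def test_identity_when_equal(self):
        assert egaba_combine(-55.0, -55.0) == pytest.approx(-55.0)

    def test_hand_value(self):
        assert egaba_combine(-74.0, -17.39) == pytest.approx(-62.68, abs=0.01)


def _two_box():
    vol = np.array([2.0, 1.0]) * 1e-15            # L (2 and 1 µm³)
    area = np.array([1.0, 1.0]) * 1e-8
    axs = np.array([1.0])                          # µm²
    dx = np.array([1.0])                           # µm
    return vol, area, axs, dx


class TestChlorideStep:
    def test_flat_profile_unchanged(self):
        vol, area, axs, dx = _two_box()
        cl = np.array([5.0, 5.0])
        out = chloride_step(cl, np.zeros(2), np.zeros(2), DiffusionParams(),
                            area, vol, axs, dx, 0.01)
        assert np.allclose(out, cl, atol=1e-15)

    def test_two_box_equilibrium_and_conservation(self):
        vol, area, axs, dx = _two_box()
        cl = np.array([10.0, 4.0])
        total0 = (cl * vol).sum()
        for _ in range(20000):
            cl = chloride_step(cl, np.zeros(2), np.zeros(2),
                               DiffusionParams(), area, vol, axs, dx, 0.01)
        expected = (10 * vol[0] + 4 * vol[1]) / vol.sum()
        assert cl == pytest.approx(expected, rel=1e-6)
        assert (cl * vol).sum() == pytest.approx(total0, rel=1e-10)

    def test_kcc2_decay_matches_reference_integration(self):
        # sealed single compartment, KCC2 only; oracle: dense-output solve_ivp
        from cldyn.mechanisms import convert_pump_strength, REFERENCE_CELL
        p_conc = 0.001
        vol = np.array([REFERENCE_CELL["volume_L"]])
        area = np.array([REFERENCE_CELL["area_cm2"]])
        p_cur = np.array([convert_pump_strength(p_conc, vol[0], area[0])])
        cl = np.array([10.0])
        dt = 0.5
        n_steps = 40000                              # 20 s
        hist = [cl[0]]
        for _ in range(n_steps):
            cl = chloride_step(cl, np.zeros(1), p_cur, DiffusionParams(),
                               area, vol, np.empty(0), np.empty(0), dt)
            hist.append(cl[0])
        sol = solve_ivp(
            lambda t, y: -p_conc * (140.0 * y - 4.0 * 135.0) * 1e-3,
            (0, n_steps * dt), [10.0], rtol=1e-10, atol=1e-12,
            dense_output=True)
        t_end = n_steps * dt
        assert cl[0] == pytest.approx(sol.sol(t_end)[0], rel=1e-3)
        # monotone decay toward the thermodynamic equilibrium
        assert np.all(np.diff(hist) < 0)
        assert cl[0] > kcc2_equilibrium_cl()
        assert kcc2_equilibrium_cl() == pytest.approx(540.0 / 140.0)

    def test_underflow_flagged_with_location(self):
        vol, area, axs, dx = _two_box()
        cl = np.array([0.01, 0.01])
        strong_efflux = np.array([-1.0, -1.0])       # nA of Cl- leaving
        with pytest.raises(NumericalFailure, match="compartment"):
            for _ in range(1000):
                cl = chloride_step(cl, strong_efflux, np.zeros(2),
                                   DiffusionParams(), area, vol, axs, dx, 0.1)

    @given(st.integers(2, 8), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_diffusion_conserves_mass(self, n, seed):
        rng = np.random.default_rng(seed)
        vol = rng.uniform(0.5, 5.0, n) * 1e-15
        cl = rng.uniform(2.0, 20.0, n)
        axs = rng.uniform(0.2, 2.0, n - 1)
        dx = rng.uniform(0.5, 5.0, n - 1)
        total0 = (cl * vol).sum()
        for _ in range(200):
            dcl = diffusion_exchange(cl, 2.03, axs, dx, vol)
            cl = cl + 0.01 * dcl
        assert (cl * vol).sum() == pytest.approx(total0, rel=1e-12)


def test_step_profile_matches_analytic_diffusion():
    """Step IC on a uniform cable vs the free-space erf solution; L² error
    shrinks as the grid refines (checked before boundaries matter)."""
    D = 2.03
    t_end = 40.0                                    # ms; sqrt(4Dt) ≈ 18 µm ≪ L/2
    L = 400.0
    errs = []
    for n in (40, 80, 160):
        dx_c = L / n
        x = (np.arange(n) + 0.5) * dx_c - L / 2
        vol = np.full(n, dx_c * 1e-15)              # unit cross-section
        axs = np.full(n - 1, 1.0)
        dxs = np.full(n - 1, dx_c)
        cl = np.where(x < 0, 10.0, 2.0)
        dt = 0.2 * dx_c ** 2 / (2 * D)
        steps = int(round(t_end / dt))
        for _ in range(steps):
            cl = cl + dt * diffusion_exchange(cl, D, axs, dxs, vol)
        analytic = 6.0 - 4.0 * erf(x / math.sqrt(4 * D * t_end))
        errs.append(math.sqrt(np.mean((cl - analytic) ** 2)))
    assert errs[0] < 0.2
    assert errs[2] < errs[0]


def test_engine_diffusion_only_conserves_chloride(make_tuned_model):
    """Mass conservation inside the full engine: all Cl⁻ fluxes off,
    non-uniform initial profile, a million steps."""
    m = make_tuned_model()
    m.g_leak_Cl[:] = 0.0
    m.p_kcc2[:] = 0.0
    m.cl0_mM[:] = np.linspace(3.0, 12.0, m.n)
    total0 = (m.cl0_mM * m.vol_L).sum()
    res = simulate(m, None, SimulationConfig(duration_ms=25000.0))
    total1 = (res.final_cl * m.vol_L).sum()
    assert total1 == pytest.approx(total0, rel=1e-8)


class TestDynamicPotassium:
    def test_rest_is_fixed_point(self, make_tuned_model):
        m = make_tuned_model()
        dk = enable_dynamic_potassium(m)
        res = simulate(m, None, SimulationConfig(
            duration_ms=10000.0, potassium_mode="dynamic"), dynamic_k=dk)
        assert np.abs(res.final_cl - m.cl0_mM).max() < 0.01 * m.cl0_mM.min()
        assert np.abs(res.final_k - 140.0).max() < 0.01 * 140.0
        assert abs(res.v_soma[-1] - res.v_soma[0]) < 0.5

    def test_tonic_fluxes_balance_initial_kcc2(self, make_tuned_model):
        # net KCC2 charge flux is zero by construction (electroneutral);
        # the tonic Cl⁻ and K⁺ fluxes equal the initial extrusion rate
        m = make_tuned_model()
        dk = enable_dynamic_potassium(m)
        assert np.array_equal(dk.tonic_cl_mM_per_ms, dk.tonic_k_mM_per_ms)
        rate = (1e-3 * m.p_kcc2 * (140.0 * m.cl0_mM - 540.0)
                * m.area_cm2 / (m.constants.F * m.vol_L))
        assert np.allclose(dk.tonic_cl_mM_per_ms, rate)

    def test_potassium_depletes_under_strong_chloride_load(self,
                                                           make_tuned_model):
        # strong distal GABA drive loads Cl⁻; KCC2 then exports K⁺ with it
        from cldyn.calibration import distal_fin_program
        m = make_tuned_model()
        dk = enable_dynamic_potassium(m)
        stim = distal_fin_program(m, 0, 400, 50.0, seed=5)
        res = simulate(m, stim, SimulationConfig(
            duration_ms=1000.0, potassium_mode="dynamic"), dynamic_k=dk)
        distal = m.section_mask("distal")
        assert res.final_cl[distal].mean() > m.cl0_mM[distal].mean() + 0.5
        assert res.final_k[distal].mean() < 140.0 - 0.1
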