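import math

import numpy as np
import pytest

from cldyn import build_default_model
from cldyn.calibration import (
    FitError, RecoveryTrace, balanced_pair_search, cl_from_egaba,
    egaba_from_current, fit_gaba_conductance, fit_recovery,
    measure_input_resistance, resting_state, tune_leaks, _passive_rin,
)
from cldyn.chloride import egaba_combine, nernst
from cldyn.synthetic import RecoveryGeneratorSpec, generate_recovery


class TestEgabaFromCurrent:
    def test_zero_current(self):
        assert egaba_from_current(0.0, 2.0, -70.0) == -70.0

    def test_hand_value(self):
        assert egaba_from_current(20.0, 2.0, -70.0) == -80.0

    def test_round_trip_with_ohmic_current(self):
        g, egaba, vhold = 1.7, -63.2, -50.0
        i = g * (vhold - egaba)
        assert egaba_from_current(i, g, vhold) == pytest.approx(egaba,
                                                                abs=1e-10)

    def test_rejects_non_positive_conductance(self):
        with pytest.raises(ValueError):
            egaba_from_current(5.0, 0.0, -70.0)


class TestClFromEgaba:
    def test_table_inversion(self):
        cl = cl_from_egaba(-77.41)
        assert cl == pytest.approx(4.25, abs=0.02)

    def test_forward_inverse_identity(self):
        for cl0 in (2.0, 4.25, 10.0, 30.0):
            egaba = egaba_combine(nernst(-1, cl0, 135.0),
                                  nernst(-1, 12.0, 23.0))
            assert cl_from_egaba(egaba) == pytest.approx(cl0, abs=1e-8)

    def test_egaba_equal_ehco3_forces_ecl_equal_ehco3(self):
        from cldyn.constants import DEFAULT_CONSTANTS
        ehco3 = nernst(-1, 12.0, 23.0)
        cl = cl_from_egaba(ehco3)
        expected = 135.0 * math.exp(ehco3 / DEFAULT_CONSTANTS.rtf_mV)
        assert cl == pytest.approx(expected, rel=1e-10)

    def test_experimental_bicarbonate_set(self):
        # the perforated-patch pipeline uses 10/25 mM bicarbonate
        cl = cl_from_egaba(-77.41, hco3_i=10.0, hco3_o=25.0)
        assert cl != pytest.approx(4.25, abs=0.02)
        egaba = egaba_combine(nernst(-1, cl, 135.0), nernst(-1, 10.0, 25.0))
        assert egaba == pytest.approx(-77.41, abs=1e-8)


class TestFitGabaConductance:
    def test_two_points_define_the_line(self):
        from cldyn.synthetic import generate_puff_currents
        rec = generate_puff_currents(-74.0, 2.5, [-90.0, -50.0])
        g, egaba = fit_gaba_conductance(rec.i_pA, rec.vhold_mV)
        assert g == pytest.approx(2.5, rel=1e-12)
        assert egaba == pytest.approx(-74.0, abs=1e-9)

    def test_single_holding_potential_rejected(self):
        with pytest.raises(ValueError):
            fit_gaba_conductance([1.0, 2.0], [-70.0, -70.0])


class TestFitRecovery:
    def test_noiseless_recovers_ground_truth(self):
        trace = generate_recovery(RecoveryGeneratorSpec())
        est = fit_recovery(trace)
        assert est.P_conc == pytest.approx(trace.meta["true_P"], rel=0.01)
        assert est.tau_s == pytest.approx(trace.meta["tau_true_s"], rel=0.01)
        assert est.P_current == pytest.approx(1.9297e-5, rel=0.02)

    def test_free_baseline_also_recovers(self):
        trace = generate_recovery(RecoveryGeneratorSpec())
        trace.baseline_mM = None
        est = fit_recovery(trace)
        assert est.P_conc == pytest.approx(0.001, rel=0.02)
        assert est.baseline_mM == pytest.approx(4.25, abs=0.05)

    def test_flat_trace_unidentifiable(self):
        t = np.arange(2.0, 40.0, 5.0)
        trace = RecoveryTrace(t, np.full(len(t), 4.25), baseline_mM=4.25)
        with pytest.raises(FitError, match="unidentifiable"):
            fit_recovery(trace)

    def test_oscillating_trace_flagged(self):
        t = np.arange(2.0, 62.0, 5.0)
        trace = RecoveryTrace(t, 8.0 + 3.0 * np.sin(t), baseline_mM=4.25)
        with pytest.raises(FitError):
            fit_recovery(trace)

    def test_noisy_monte_carlo_unbiased(self):
        estimates = []
        for seed in range(100):
            trace = generate_recovery(
                RecoveryGeneratorSpec(noise_sd_mM=0.3, seed=seed))
            estimates.append(fit_recovery(trace).P_conc)
        estimates = np.array(estimates)
        assert np.median(estimates) == pytest.approx(0.001, rel=0.10)
        # no systematic bias sign: both signs of error occur amply
        assert 20 < (estimates > 0.001).sum() < 80

    @pytest.mark.parametrize("noise,tol", [(0.3, 0.15), (0.03, 0.02),
                                           (0.003, 0.002)])
    def test_consistency_error_shrinks_with_noise(self, noise, tol):
        trace = generate_recovery(
            RecoveryGeneratorSpec(noise_sd_mM=noise, seed=123))
        est = fit_recovery(trace)
        assert est.P_conc == pytest.approx(0.001, rel=tol)


class TestTuneLeaks:
    def test_achieves_target_rin(self, make_tuned_model):
        m = make_tuned_model(refine=True)
        assert measure_input_resistance(m) == pytest.approx(365.0, rel=0.01)

    def test_idempotent(self):
        m = build_default_model()
        first = tune_leaks(m, refine=False)
        second = tune_leaks(m, refine=False)
        assert second.leak_scale == pytest.approx(first.leak_scale, rel=1e-3)

    def test_density_doubling_roughly_halves_rin(self, tuned_model):
        # exactly 1/2 for an isopotential cell; slightly above because the
        # thin distal dendrite and axon are partially decoupled by axial
        # resistance (cable loading grows like 1/sqrt(g) there)
        rin = _passive_rin(tuned_model, tuned_model.leak_scale)
        rin2 = _passive_rin(tuned_model, 2 * tuned_model.leak_scale)
        assert 0.5 <= rin2 / rin < 0.6

    def test_emergent_rest_matches_table_defaults(self, make_tuned_model):
        tuned = tune_leaks(build_default_model(), refine=False)
        assert tuned.v_rest_mV == pytest.approx(-71.35, rel=0.02)
        assert tuned.cl_rest_mM == pytest.approx(4.25, abs=0.1)

    def test_ratio_exact_after_tuning(self, tuned_model):
        gk, gna, gcl = (tuned_model.g_leak_K[0], tuned_model.g_leak_Na[0],
                        tuned_model.g_leak_Cl[0])
        assert gna / gk == pytest.approx(0.23, rel=1e-12)
        assert gcl / gk == pytest.approx(0.4, rel=1e-12)

    def test_rejects_bad_target(self):
        with pytest.raises(ValueError):
            tune_leaks(build_default_model(), target_rin_MOhm=-10.0)


class TestRestingState:
    def test_electroneutral_vs_electrogenic_kcc2(self, tuned_model):
        v0, cl0 = resting_state(tuned_model)
        v1, cl1 = resting_state(tuned_model, electrogenic_kcc2=True)
        assert v1 > v0 + 2.0       # charge-carrying extrusion depolarises
        assert cl1 > cl0


class TestBalancedPairSearch:
    def test_rate_monotone_in_excitation_and_band(self, tuned_model):
        df, pairs = balanced_pair_search(
            tuned_model, e_counts=(150, 400), i_counts=(50,),
            trials=1, tol_hz=1e6, duration_ms=600.0, seed=4)
        r_low = df[df.n_exc == 150].rate_hz.iloc[0]
        r_high = df[df.n_exc == 400].rate_hz.iloc[0]
        assert r_high >= r_low
        # tolerance band wider than the observed range returns every cell
        assert len(pairs) == len(df)
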