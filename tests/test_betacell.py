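"""Beta-cell indices, secretion-model forward/fit round trips, Matsuda, composite."""

import numpy as np
import pandas as pd
import pytest

from autonomic_beta import betacell as bc
from autonomic_beta.synthcohort import GLUCOSE_TEMPLATES


def record(glucose, cpeptide, insulin=None):
    glucose = np.asarray(glucose, float)
    cpeptide = np.asarray(cpeptide, float)
    if insulin is None:
        insulin = 0.12 * cpeptide
    return bc.OGTTRecord(glucose, cpeptide, insulin)


class TestEligibility:
    @pytest.mark.parametrize(
        "insulin_use,fg,expected",
        [(False, 11.1, False), (False, 11.0, True), (True, 5.0, False), (False, 5.0, True)],
    )
    def test_insulin_use_and_fasting_glucose_threshold(self, insulin_use, fg, expected):
        assert bc.ogtt_eligibility(insulin_use, fg) is expected


class TestFormulaIndices:
    def test_cpeptidogenic_worked_example(self):
        rec = record([5.0, 6.0, 8.0, 8.0, 7.0, 6.0, 5.5], [600, 900, 1500, 1500, 1200, 900, 700])
        assert bc.cpeptidogenic_index(rec) == pytest.approx(900.0 / 3.0)

    def test_cpeptidogenic_zero_when_cp_flat(self):
        rec = record([5.0, 6.0, 8.0, 8.0, 7.0, 6.0, 5.5], np.full(7, 600.0))
        assert bc.cpeptidogenic_index(rec) == 0.0

    def test_cpeptidogenic_flagged_missing_on_zero_denominator(self):
        rec = record([5.0, 6.0, 5.0, 8.0, 7.0, 6.0, 5.5], [600, 900, 1500, 1500, 1200, 900, 700])
        assert np.isnan(bc.cpeptidogenic_index(rec))

    def test_cpeptidogenic_ignores_samples_other_than_0_and_30(self):
        a = record([5.0, 6.0, 8.0, 8.0, 7.0, 6.0, 5.5], [600, 900, 1500, 1500, 1200, 900, 700])
        b_ = record([5.0, 9.9, 8.0, 4.4, 9.1, 7.7, 6.6], [600, 111, 1500, 222, 333, 444, 555])
        assert bc.cpeptidogenic_index(a) == bc.cpeptidogenic_index(b_)

    def test_auc_constant_and_triangle(self):
        assert bc.auc_trapezoid([0, 120], [5.0, 5.0]) == pytest.approx(600.0)
        assert bc.auc_trapezoid([0, 120], [0.0, 120.0]) == pytest.approx(7200.0)

    def test_overall_secretion_constant_curves(self):
        rec = record(np.full(7, 5.0), np.full(7, 600.0))
        assert bc.overall_insulin_secretion(rec) == pytest.approx(120.0)

    def test_overall_secretion_equals_ratio_of_time_averages(self):
        rng = np.random.default_rng(1)
        rec = record(rng.uniform(4, 12, 7), rng.uniform(400, 2500, 7))
        cp_avg = bc.auc_trapezoid(rec.t_min, rec.cpeptide_pmol_l) / 120.0
        g_avg = bc.auc_trapezoid(rec.t_min, rec.glucose_mmol_l) / 120.0
        assert bc.overall_insulin_secretion(rec) == pytest.approx(cp_avg / g_avg)


class TestMatsuda:
    def test_worked_example(self):
        # G0 = 90 mg/dL, I0 = 10 uU/mL, Gmean = 120, Imean = 50
        g_mgdl = np.array([90.0] + [125.0] * 6)  # mean 120
        i_uu = np.array([10.0] + [170.0 / 3.0] * 6)  # mean 50
        rec = bc.OGTTRecord(g_mgdl / bc.MGDL_PER_MMOL, np.full(7, 600.0), i_uu * bc.PMOL_PER_MICROU)
        assert bc.matsuda_index(rec) == pytest.approx(1e4 / np.sqrt(5.4e6), rel=1e-9)
        assert bc.matsuda_index(rec) == pytest.approx(4.30, abs=0.01)

    def test_all_equal_reduces_to_inverse_product(self):
        rec = bc.OGTTRecord(np.full(7, 90.0 / bc.MGDL_PER_MMOL), np.full(7, 600.0), np.full(7, 60.0))
        assert bc.matsuda_index(rec) == pytest.approx(1e4 / (90.0 * 10.0))

    def test_doubling_insulin_halves_the_index(self):
        rng = np.random.default_rng(2)
        g, cp, ins = rng.uniform(4, 10, 7), np.full(7, 600.0), rng.uniform(30, 400, 7)
        one = bc.matsuda_index(bc.OGTTRecord(g, cp, ins))
        two = bc.matsuda_index(bc.OGTTRecord(g, cp, 2 * ins))
        assert two == pytest.approx(one / 2.0)


class TestKinetics:
    def test_deterministic_and_positive(self):
        a = bc.cpeptide_kinetics(55, "F", 24.0, "NGM")
        b_ = bc.cpeptide_kinetics(55, "F", 24.0, "NGM")
        assert a == b_
        assert min(a.k01, a.k12, a.k21, a.v_d) > 0

    def test_volume_monotone_in_body_size(self):
        small = bc.cpeptide_kinetics(60, "M", 22.0, "NGM")
        large = bc.cpeptide_kinetics(60, "M", 29.0, "NGM")
        assert large.v_d > small.v_d

    def test_class_specific_slow_halflife(self):
        ngm = bc.cpeptide_kinetics(60, "M", 26.0, "NGM")
        t2d = bc.cpeptide_kinetics(60, "M", 26.0, "T2D")
        assert ngm != t2d

    @pytest.mark.parametrize("kwargs", [
        dict(age=10, sex="M", bmi=26.0, gms="NGM"),
        dict(age=60, sex="M", bmi=8.0, gms="NGM"),
        dict(age=60, sex="X", bmi=26.0, gms="NGM"),
        dict(age=60, sex="M", bmi=26.0, gms="bad"),
    ])
    def test_out_of_range_inputs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            bc.cpeptide_kinetics(**kwargs)


class TestForwardModel:
    def test_flat_glucose_gives_steady_state(self, ngm_kinetics):
        cp = bc.forward_simulate_ogtt(np.full(7, 5.0), ngm_kinetics, 70.0, 100.0, 0.0)
        expected = 70.0 * ngm_kinetics.bsa_m2 / (ngm_kinetics.k01 * ngm_kinetics.v_d)
        np.testing.assert_allclose(cp, expected, rtol=1e-9)

    def test_doubling_slope_doubles_incremental_response(self, ngm_kinetics, ngm_glucose):
        base = bc.forward_simulate_ogtt(ngm_glucose, ngm_kinetics, 70.0, 50.0, 0.0)
        double = bc.forward_simulate_ogtt(ngm_glucose, ngm_kinetics, 70.0, 100.0, 0.0)
        inc1 = bc.auc_trapezoid(bc.OGTT_TIMES_MIN, base - base[0])
        inc2 = bc.auc_trapezoid(bc.OGTT_TIMES_MIN, double - double[0])
        assert inc2 == pytest.approx(2.0 * inc1, rel=1e-6)

    def test_invalid_parameters_rejected(self, ngm_kinetics, ngm_glucose):
        with pytest.raises(ValueError):
            bc.forward_simulate_ogtt(ngm_glucose, ngm_kinetics, -1.0, 100.0, 0.0)
        with pytest.raises(ValueError):
            bc.forward_simulate_ogtt(ngm_glucose, ngm_kinetics, 70.0, 100.0, 0.0, potentiation_ratio=0.0)


class TestDeconvolution:
    def test_steady_state_record_gives_flat_clearance_isr(self, ngm_kinetics):
        kin = ngm_kinetics
        cp0 = 500.0
        _, isr = bc.deconvolve_isr(np.full(7, cp0), kin)
        np.testing.assert_allclose(isr, kin.k01 * cp0 * kin.v_d / kin.bsa_m2, rtol=1e-6)

    def test_round_trip_smooth_isr_under_five_percent(self, ngm_kinetics, ngm_glucose):
        cp = bc.forward_simulate_ogtt(ngm_glucose, ngm_kinetics, 70.0, 100.0, 0.0)
        edges, isr = bc.deconvolve_isr(cp, ngm_kinetics)
        grid, g, _ = bc._dense_glucose(ngm_glucose, bc.OGTT_TIMES_MIN, 1.0)
        truth = 70.0 + 100.0 * (g - g[0])
        truth_bins = np.array([truth[(grid >= e) & (grid < e + 5)].mean() for e in edges])
        rmse = np.sqrt(np.mean((isr - truth_bins) ** 2))
        assert rmse < 0.05 * truth_bins.mean()

    def test_large_regularization_tends_to_affine_profile(self, ngm_kinetics, ngm_glucose):
        cp = bc.forward_simulate_ogtt(ngm_glucose, ngm_kinetics, 70.0, 100.0, 400.0)
        _, isr = bc.deconvolve_isr(cp, ngm_kinetics, regularization=1e8)
        # second differences vanish: the limit is the best-fitting affine ISR
        assert np.max(np.abs(np.diff(isr, 2))) < 1e-3 * isr.mean()

    def test_negative_regularization_rejected(self, ngm_kinetics):
        with pytest.raises(ValueError):
            bc.deconvolve_isr(np.full(7, 500.0), ngm_kinetics, regularization=-1.0)


class TestModelFit:
    def test_noise_free_round_trip_recovers_slope(self, ngm_kinetics, ngm_glucose):
        cp = bc.forward_simulate_ogtt(ngm_glucose, ngm_kinetics, 70.0, 100.0, 800.0, 1.0)
        res = bc.BetaCellModel(record(ngm_glucose, cp), ngm_kinetics).fit()
        assert res.glucose_sensitivity == pytest.approx(100.0, rel=0.05)
        assert res.potentiation_ratio == pytest.approx(1.0, abs=0.05)

    def test_null_rate_sensitivity_recovered_near_zero(self, ngm_kinetics, ngm_glucose):
        cp = bc.forward_simulate_ogtt(ngm_glucose, ngm_kinetics, 70.0, 100.0, 0.0, 1.0)
        res = bc.BetaCellModel(record(ngm_glucose, cp), ngm_kinetics).fit()
        assert abs(res.rate_sensitivity) < 0.05 * 800.0  # 5% of the generator scale

    def test_true_potentiation_recovered(self, ngm_kinetics, ngm_glucose):
        cp = bc.forward_simulate_ogtt(ngm_glucose, ngm_kinetics, 70.0, 100.0, 500.0, 1.6)
        res = bc.BetaCellModel(record(ngm_glucose, cp), ngm_kinetics).fit()
        assert res.potentiation_ratio == pytest.approx(1.6, rel=0.15)

    def test_summary_is_one_row(self, ngm_kinetics, ngm_glucose):
        cp = bc.forward_simulate_ogtt(ngm_glucose, ngm_kinetics, 70.0, 100.0, 0.0)
        tab = bc.BetaCellModel(record(ngm_glucose, cp), ngm_kinetics).fit().summary()
        assert len(tab) == 1 and "glucose_sensitivity" in tab


class TestComposite:
    def _profiles(self, n=20, seed=3):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({c: rng.uniform(1, 100, n) for c in bc.BETACELL_INDICES})

    def test_restandardized_to_mean_zero_sd_one(self):
        z = bc.betacell_composite(self._profiles())
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_order_preserved_for_dominating_subject(self):
        df = pd.DataFrame(
            {c: [10.0, 20.0] for c in bc.BETACELL_INDICES}
        )
        z = bc.betacell_composite(df)
        assert z.iloc[1] > z.iloc[0]
        assert z.iloc[1] == pytest.approx(1 / np.sqrt(2))  # sample-SD convention at n=2

    def test_incomplete_cases_rejected(self):
        df = self._profiles()
        df.loc[0, "rate_sensitivity"] = np.nan
        with pytest.raises(ValueError, match="complete"):
            bc.betacell_composite(df)

    def test_zero_variance_rejected(self):
        df = self._profiles()
        df["potentiation_ratio"] = 1.5
        with pytest.raises(ValueError, match="zero variance"):
            bc.betacell_composite(df)
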