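"""Synthetic cohort generator: SEM path algebra, covariate marginals, raw signals."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from autonomic_beta import betacell as bc
from autonomic_beta import hrv
from autonomic_beta import synthcohort as sc


class TestSEMPaths:
    def test_single_confounder_reproduces_crude_adjusted_pair(self):
        cfg = sc.solve_sem_paths(-0.070, -0.055, [("c", 0.3, 1.0)])
        assert cfg.confounders[0].b["outcome"] == pytest.approx(-0.05)
        assert cfg.population_crude("outcome") == pytest.approx(-0.070, abs=1e-12)
        assert cfg.population_adjusted("outcome") == pytest.approx(-0.055, abs=1e-12)

    def test_no_confounding_means_crude_equals_adjusted(self):
        cfg = sc.solve_sem_paths(-0.055, -0.055, [("c", 0.3, 1.0)])
        assert cfg.confounders[0].b["outcome"] == 0.0
        assert cfg.population_crude("outcome") == pytest.approx(-0.055)

    def test_pure_confounding_with_zero_direct_effect(self):
        cfg = sc.SEMConfig(
            100, "x", {"y": 0.0}, [sc.ConfounderPath("c", 0.5, {"y": 0.5})]
        )
        assert cfg.population_crude("y") == pytest.approx(0.25)
        assert cfg.population_adjusted("y") == pytest.approx(0.0)

    def test_infeasible_gap_raises(self):
        with pytest.raises(ValueError):
            sc.solve_sem_paths(0.9, -0.9, [("c", 0.5, 1.0)])  # |b| would exceed 1

    def test_standardization_residuals_solved_not_free(self):
        cfg = sc.calibrate_ladder_sem(
            "x", {"y": {"crude": -0.070, "m3b": -0.055}}, n_subjects=5000, seed=0
        )
        # implied variances are exactly 1: residual SDs exist and close the sum
        sx = cfg.residual_sd_exposure()
        assert 0 < sx < 1
        total = sx**2 + sum(c.a**2 for c in cfg.confounders)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_ladder_calibration_matches_every_stage(self):
        targets = {"y": {"crude": -0.070, "m1": -0.063, "m2": -0.067, "m3a": -0.059, "m3b": -0.055}}
        cfg = sc.calibrate_ladder_sem("x", targets)
        controlled = []
        expected = [-0.070, -0.063, -0.067, -0.059, -0.055]
        stages = ["crude", "m1", "m2", "m3a", "m3b"]
        for stage, value in zip(stages, expected):
            controlled += [c.name for c in cfg.confounders if c.ladder_block == stage]
            # internal sign convention is per SD higher exposure
            assert cfg.population_adjusted("y", controlled) == pytest.approx(-value, abs=1e-12)


class TestDrawScores:
    def _cfg(self, n=2007, seed=1):
        return sc.calibrate_ladder_sem(
            "hrv_time_z",
            {"betacell_composite_z": {"crude": -0.070, "m3b": -0.055}},
            n_subjects=n,
            seed=seed,
        )

    def test_row_count_and_determinism(self):
        df1 = sc.draw_cohort_scores(self._cfg())
        df2 = sc.draw_cohort_scores(self._cfg())
        assert len(df1) == 2007
        assert df1.equals(df2)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            sc.draw_cohort_scores(self._cfg(n=5))

    def test_large_sample_crude_converges_to_target(self):
        df = sc.draw_cohort_scores(self._cfg(n=200_000, seed=11))
        x = df["hrv_time_z"].to_numpy()
        y = df["betacell_composite_z"].to_numpy()
        crude = np.polyfit(x / x.std(ddof=1), y / y.std(ddof=1), 1)[0]
        assert crude == pytest.approx(0.070, abs=0.005)  # per SD higher exposure

    def test_antithetic_pair_shares_structure_and_cancels_noise(self):
        cfg = self._cfg(n=3000, seed=17)
        a, b = sc.draw_antithetic_pair(cfg)
        pd.testing.assert_series_equal(a["hrv_time_z"], b["hrv_time_z"])
        pd.testing.assert_series_equal(a["age"], b["age"])
        # residual sum flips sign: the pair's outcome mean is the structural part
        d = cfg.direct_effects["betacell_composite_z"]
        structural = d * a["hrv_time_z"]
        for c in cfg.confounders:
            mu, sd = sc.SCORE_COVARIATE_SCALES.get(c.name, (0.0, 1.0))
            structural = structural + c.b.get("betacell_composite_z", 0.0) * (a[c.name] - mu) / sd
        mean_y = 0.5 * (a["betacell_composite_z"] + b["betacell_composite_z"])
        np.testing.assert_allclose(mean_y, structural, atol=1e-10)

    def test_extras_present_with_expected_levels(self):
        df = sc.draw_cohort_scores(self._cfg(n=500))
        assert set(df["gms"]) <= {"NGM", "prediabetes", "T2D"}
        assert set(df["education"]) <= {"low", "middle", "high"}


class TestCovariates:
    def test_age_moment_matched_after_truncation(self):
        df = sc.draw_covariates(100_000, seed=4)
        assert df["age"].mean() == pytest.approx(60.0, abs=0.1)
        assert df["age"].std() == pytest.approx(8.0, abs=0.1)
        assert df["age"].min() >= 40.0 and df["age"].max() <= 75.0

    def test_gms_mix_matches_design_proportions(self):
        df = sc.draw_covariates(20_007, seed=5)
        frac = (df["gms"] == "T2D").mean()
        assert frac == pytest.approx(0.24, abs=0.01)
        assert (df["sex"] == "M").mean() == pytest.approx(0.52, abs=0.01)

    def test_deterministic_given_seed(self):
        assert sc.draw_covariates(100, seed=6).equals(sc.draw_covariates(100, seed=6))

    def test_insulin_use_only_in_t2d(self):
        df = sc.draw_covariates(5000, seed=7)
        assert (df.loc[df["insulin_use"] == 1, "gms"] == "T2D").all()


class TestBeatSynthesis:
    def test_zero_modulation_gives_constant_rr(self):
        mod = sc.ModulationSpec(
            circadian_ms=0, lf_ms=0, hf_ms=0, jitter_ms=0,
            ectopic_fraction=0, artifact_fraction=0, amplitude_slope=0,
        )
        beats = sc.synthesize_beat_series(duration_h=1.0, mean_rr_ms=800, modulation=mod, seed=0)
        nn = hrv.extract_nn(beats)
        assert hrv.time_domain(nn)["sdnn_ms"] < 1e-6

    def test_hf_only_modulation_lands_in_hf_band(self):
        mod = sc.ModulationSpec(
            circadian_ms=0, lf_ms=0, hf_ms=40, jitter_ms=0,
            ectopic_fraction=0, artifact_fraction=0, amplitude_slope=0,
        )
        beats = sc.synthesize_beat_series(duration_h=19.0, modulation=mod, seed=1)
        fd = hrv.frequency_domain(hrv.extract_nn(beats))
        assert fd["hf_ms2"] / fd["tp_ms2"] > 0.9

    def test_ectopic_fraction_bookkeeping(self):
        mod = sc.ModulationSpec(ectopic_fraction=0.05, artifact_fraction=0.0)
        beats = sc.synthesize_beat_series(duration_h=24.0, modulation=mod, seed=2)
        frac = np.mean(beats.label == hrv.ECTOPIC)
        assert frac == pytest.approx(0.05, abs=0.005)

    def test_times_strictly_increasing_both_methods(self):
        for method in ("integral", "sampled"):
            beats = sc.synthesize_beat_series(duration_h=0.5, seed=3, method=method)
            assert np.all(np.diff(beats.beat_time_s) > 0)

    @pytest.mark.parametrize("kwargs", [dict(duration_h=0.0), dict(mean_rr_ms=100.0)])
    def test_preconditions(self, kwargs):
        with pytest.raises(ValueError):
            sc.synthesize_beat_series(**kwargs)


class TestOGTTSynthesis:
    def _truth(self, **over):
        base = dict(
            subject_id="S0", latent_autonomic=0.0, gms="NGM",
            glucose_sensitivity=100.0, rate_sensitivity=700.0,
            potentiation_ratio=1.0, basal_secretion=70.0,
            covariates={"age": 60.0, "sex": "M", "bmi": 26.0},
        )
        base.update(over)
        return sc.SubjectTruth(**base)

    def test_bit_identical_given_seed(self):
        a = sc.synthesize_ogtt(self._truth(), seed=9)
        b = sc.synthesize_ogtt(self._truth(), seed=9)
        np.testing.assert_array_equal(a.cpeptide_pmol_l, b.cpeptide_pmol_l)

    def test_noise_free_round_trip_recovers_glucose_sensitivity(self):
        truth = self._truth()
        rec = sc.synthesize_ogtt(truth, noise_cv=0.0, seed=0)
        kin = bc.cpeptide_kinetics(60.0, "M", 26.0, "NGM")
        res = bc.BetaCellModel(rec, kin).fit()
        assert res.glucose_sensitivity == pytest.approx(100.0, rel=0.05)

    def test_prediabetes_insulin_exceeds_ngm_and_t2d(self):
        recs = {
            g: sc.synthesize_ogtt(self._truth(gms=g), noise_cv=0.0, seed=0)
            for g in ("NGM", "prediabetes", "T2D")
        }
        peak = {g: r.insulin_pmol_l.max() for g, r in recs.items()}
        assert peak["prediabetes"] > peak["NGM"]
        assert peak["prediabetes"] > peak["T2D"]

    def test_invalid_truth_rejected(self):
        with pytest.raises(ValueError):
            self._truth(glucose_sensitivity=-5.0)


class TestSubjectStreams:
    def test_subject_truth_independent_of_cohort_size(self):
        small = sc.draw_subject_truths(3, seed=13)
        large = sc.draw_subject_truths(6, seed=13)
        assert small[2].glucose_sensitivity == large[2].glucose_sensitivity
        assert small[2].latent_autonomic == large[2].latent_autonomic


def test_signal_score_consistency():
    """Composites computed from noise-free synthesized signals track the
    generator's drawn score-level composites (r > 0.99)."""
    import pandas as pd

    n = 100
    lat = np.random.default_rng(3).standard_normal(n)
    mod = sc.ModulationSpec(ectopic_fraction=0.0, artifact_fraction=0.0)
    rows = []
    for k in range(n):
        beats = sc.synthesize_beat_series(
            latent_autonomic=lat[k], duration_h=24.0, seed=1000 + k, modulation=mod
        )
        nn = hrv.extract_nn(beats)
        prof = hrv.time_domain(nn)
        prof.update(hrv.frequency_domain(nn))
        rows.append(prof)
    computed = hrv.hrv_composites(pd.DataFrame(rows))
    drawn = sc.score_level_composites(lat, mod)
    assert np.corrcoef(computed["hrv_time_z"], drawn["hrv_time_score"])[0, 1] > 0.99
    assert np.corrcoef(computed["hrv_freq_z"], drawn["hrv_freq_score"])[0, 1] > 0.99
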