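import numpy as np
import pandas as pd
import pytest

from youngbmi import ConfigError, DomainError, SimConfig, simulate_cohort
from youngbmi.simulate import inject_outliers, measurement_model

from conftest import make_config


class TestMeasurementModel:
    def test_height_floored_to_next_lower_quarter_inch(self):
        # 170 cm = 66.9291 in -> 66.75 in -> 169.545 cm
        h, _ = measurement_model(170.0, 70.0)
        assert h == pytest.approx(169.545, abs=1e-3)

    def test_flooring_is_a_fixed_point(self):
        h1, w1 = measurement_model(170.0, 70.0)
        h2, w2 = measurement_model(h1, w1)
        assert h2 == pytest.approx(h1, abs=1e-9)
        assert w2 == pytest.approx(w1, abs=1e-9)

    def test_weight_rounded_half_up_to_5_lbs(self):
        # 70 kg = 154.32 lb -> 155 lb -> 70.31 kg
        _, w = measurement_model(170.0, 70.0)
        assert w == pytest.approx(70.31, abs=5e-3)

    def test_identity_when_rounding_disabled(self):
        h, w = measurement_model(170.123, 70.456, rounding_enabled=False)
        assert (h, w) == (170.123, 70.456)

    def test_rejects_non_positive_inputs(self):
        with pytest.raises(DomainError):
            measurement_model(-1.0, 70.0)
        with pytest.raises(DomainError):
            measurement_model(170.0, 0.0)


class TestInjectOutliers:
    def test_zero_probability_is_identity(self):
        rng = np.random.default_rng(0)
        h = np.linspace(150, 160, 20)
        out, n = inject_outliers(h, 0.0, (2.5, 10.0), rng)
        assert n == 0
        np.testing.assert_array_equal(out, h)

    def test_certain_replacement_with_fixed_magnitude(self):
        rng = np.random.default_rng(0)
        h = np.full(50, 170.0)
        out, n = inject_outliers(h, 1.0, (5.0, 5.0), rng)
        assert n == 50
        np.testing.assert_allclose(np.abs(out - h), 5.0)

    def test_replacement_count_matches_binomial_expectation(self):
        rng = np.random.default_rng(1)
        h = np.full(10_000, 170.0)
        _, n = inject_outliers(h, 0.01, (2.5, 10.0), rng)
        # mean 100, sd ~10; 4 sigma band
        assert 60 <= n <= 140


class TestSimulateCohort:
    def test_every_subject_is_eligible_by_construction(self):
        cfg = make_config(n_subjects=100, seed=42)
        exams, _ = simulate_cohort(cfg)
        by_subject = exams.groupby("subject_id")["age"]
        assert exams["subject_id"].nunique() == 100
        assert by_subject.min().le(40).all()
        assert by_subject.max().gt(40).all()

    def test_identical_seed_gives_identical_output(self):
        cfg = make_config(n_subjects=40, seed=9)
        exams1, truth1 = simulate_cohort(cfg)
        exams2, truth2 = simulate_cohort(cfg)
        assert exams1.to_csv(index=False) == exams2.to_csv(index=False)
        assert truth1.exams.to_csv(index=False) == truth2.exams.to_csv(index=False)

    def test_noise_free_recorded_height_equals_true_height(self):
        exams, truth = simulate_cohort(make_config(
            n_subjects=30, height_noise_sd=0.0, outlier_prob=0.0,
            rounding_enabled=False, seed=5))
        merged = exams.merge(truth.exams, on=["subject_id", "age"])
        np.testing.assert_allclose(merged["height_cm"], merged["true_height"],
                                   atol=1e-9)

    def test_true_height_constant_before_onset_then_non_increasing(self, small_cohort):
        _, _, truth = small_cohort
        merged = truth.exams.merge(truth.subjects, on="subject_id")
        young = merged[merged["age"] <= 40.0]
        np.testing.assert_allclose(young["true_height"],
                                   young["true_young_height"], atol=1e-9)
        for _, grp in truth.exams.groupby("subject_id"):
            heights = grp.sort_values("age")["true_height"].to_numpy()
            assert np.all(np.diff(heights) <= 1e-12)

    def test_height_loss_calibration_women(self):
        """Mean true height loss 40->80 matches shrink_rate * 40 (4.8 cm)."""
        cfg = make_config(n_subjects=1000, female_fraction=1.0, seed=2)
        _, truth = simulate_cohort(cfg)
        loss = truth.subjects["true_shrink_rate"] * 40.0
        assert loss.mean() == pytest.approx(4.8, abs=0.2)

    def test_height_loss_calibration_men(self):
        cfg = make_config(n_subjects=1000, female_fraction=0.0, seed=2)
        _, truth = simulate_cohort(cfg)
        loss = truth.subjects["true_shrink_rate"] * 40.0
        assert loss.mean() == pytest.approx(3.6, abs=0.2)

    def test_young_bmi_within_configured_truncation_range(self, small_cohort):
        _, _, truth = small_cohort
        sub = truth.subjects
        women = sub[sub["sex"] == "F"]["true_young_bmi"]
        men = sub[sub["sex"] == "M"]["true_young_bmi"]
        assert women.between(17.0, 35.0).all()
        assert men.between(19.0, 35.0).all()

    def test_prediabetes_prevalence_ratio_calibrated_at_age_50(self):
        """Obese vs non-obese pre-diabetes prevalence near age 50 recovers
        the configured risk ratio (2.8 for women)."""
        cfg = make_config(n_subjects=2000, female_fraction=1.0, seed=4)
        _, truth = simulate_cohort(cfg)
        window = truth.exams[truth.exams["age"].between(48.0, 52.0)]
        p_obese = window[window["true_obese"]]["prediabetes"].mean()
        p_non = window[~window["true_obese"]]["prediabetes"].mean()
        assert p_obese / p_non == pytest.approx(2.8, abs=0.6)

    def test_glucose_consistent_with_drawn_state(self, small_cohort):
        _, exams, truth = small_cohort
        merged = exams.merge(truth.exams, on=["subject_id", "age"])
        g = merged["glucose_mgdl"]
        assert (g[merged["diabetes"]] > 200).all()
        pre = merged["prediabetes"]
        assert ((g[pre] > 140) & (g[pre] <= 200)).all()
        neither = ~merged["diabetes"] & ~pre
        assert (g[neither] <= 140).all()

    def test_blood_pressure_consistent_with_drawn_state(self, small_cohort):
        _, exams, truth = small_cohort
        merged = exams.merge(truth.exams, on=["subject_id", "age"])
        htn_rule = (merged["med_flag"] | (merged["sbp_mmhg"] >= 140)
                    | (merged["dbp_mmhg"] >= 90))
        assert (htn_rule == merged["hypertension"]).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            make_config(height_noise_sd=-1.0)
        with pytest.raises(ConfigError):
            make_config(outlier_prob=1.5)
        with pytest.raises(ConfigError):
            make_config(shrink_onset_age=90.0)
        with pytest.raises(ConfigError):
            make_config(young_height_mean_f=float("nan"))
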