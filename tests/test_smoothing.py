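import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from youngbmi import (DomainError, TooFewPointsError, bmi_consistency_filter,
                      lowess_fit, reject_outliers, smooth_with_rejection)

from conftest import tricube_wls_oracle


class TestLowessFit:
    def test_reproduces_exact_line(self):
        ages = np.arange(30.0, 60.0, 2.0)
        values = 100.0 - 0.1 * ages
        fitted = lowess_fit(ages, values, frac=0.6)
        np.testing.assert_allclose(fitted, values, atol=1e-8)

    def test_reproduces_constant(self):
        ages = np.array([30.0, 35.0, 41.0, 50.0, 62.0])
        fitted = lowess_fit(ages, np.full(5, 160.0), frac=0.6)
        np.testing.assert_allclose(fitted, 160.0, atol=1e-9)

    def test_too_few_points_signalled(self):
        with pytest.raises(TooFewPointsError):
            lowess_fit([30.0, 32.0, 34.0], [160.0, 160.0, 160.0])

    def test_requires_strictly_increasing_ages(self):
        with pytest.raises(DomainError):
            lowess_fit([30.0, 30.0, 34.0, 36.0], [1.0, 2.0, 3.0, 4.0])

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("frac", [0.5, 0.6, 1.0])
    def test_agrees_with_direct_tricube_wls_oracle(self, seed, frac):
        """For n <= 8, the fit matches an independent pointwise
        tricube-weighted least-squares evaluation."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        ages = np.sort(rng.uniform(30.0, 80.0, n))
        values = 160.0 + rng.normal(0.0, 2.0, n)
        fitted = lowess_fit(ages, values, frac=frac)
        expected = tricube_wls_oracle(ages, values, frac)
        np.testing.assert_allclose(fitted, expected, rtol=1e-8, atol=1e-8)

    def test_spike_is_attenuated_toward_the_line(self):
        ages = np.arange(40.0, 60.0, 2.0)
        line = 170.0 - 0.1 * (ages - 40.0)
        values = line.copy()
        values[4] += 8.0
        fitted = lowess_fit(ages, values, frac=0.6)
        off_spike = np.arange(len(ages)) != 4
        assert np.all(np.abs(fitted[off_spike] - line[off_spike]) < 8.0)
        # oracle agreement on the contaminated series as well
        np.testing.assert_allclose(fitted, tricube_wls_oracle(ages, values, 0.6),
                                   rtol=1e-8, atol=1e-8)


class TestRejectOutliers:
    def _series(self, residuals):
        fitted = np.full(len(residuals), 100.0)
        return fitted + np.asarray(residuals, dtype=float), fitted

    def test_six_sigma_and_floor_rule(self):
        raw, fitted = self._series([0.1, 0.1, 0.2, 0.3, 2.0])
        flags = reject_outliers(raw, fitted, abs_floor=1.0)
        # median residual 0.2 -> 6x = 1.2; only the 2.0 point exceeds both rules
        np.testing.assert_array_equal(flags, [False, False, False, False, True])

    def test_absolute_floor_dominates(self):
        raw, fitted = self._series([0.1, 0.1, 0.1, 0.1, 0.9])
        flags = reject_outliers(raw, fitted, abs_floor=1.0)
        assert not flags.any()  # 0.9 > 6*0.1 but below the 1 cm floor

    def test_zero_residuals_unflagged(self):
        raw, fitted = self._series([0.0] * 5)
        assert not reject_outliers(raw, fitted, abs_floor=1.0).any()

    @given(st.lists(st.floats(min_value=-3.0, max_value=3.0,
                              allow_nan=False), min_size=1, max_size=12))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_matches_brute_force_rule(self, residuals):
        raw, fitted = self._series(residuals)
        flags = reject_outliers(raw, fitted, abs_floor=1.0)
        resid = np.abs(np.asarray(residuals))
        expected = (resid > 6.0 * np.median(resid)) & (resid >= 1.0)
        np.testing.assert_array_equal(flags, expected)


class TestSmoothWithRejection:
    def test_spike_flagged_and_refit_recovers_line(self):
        ages = np.arange(40.0, 60.0, 2.0)
        line = 170.0 - 0.12 * (ages - 40.0)
        values = line.copy()
        values[5] += 5.0
        result = smooth_with_rejection(ages, values, abs_floor=1.0, frac=0.6)
        assert result.smoothed
        assert result.outlier_flags[5]
        assert result.outlier_flags.sum() == 1
        np.testing.assert_allclose(result.fitted, line, atol=0.1)

    def test_rejection_is_idempotent_on_the_refit(self):
        ages = np.arange(40.0, 60.0, 2.0)
        values = 170.0 - 0.12 * (ages - 40.0)
        values[5] += 5.0
        result = smooth_with_rejection(ages, values, abs_floor=1.0, frac=0.6)
        flags_again = reject_outliers(values, result.fitted, abs_floor=1.0)
        np.testing.assert_array_equal(flags_again, result.outlier_flags)

    def test_short_series_passed_through(self):
        ages = np.array([36.0, 38.0, 44.0])
        values = np.array([170.0, 169.5, 169.0])
        result = smooth_with_rejection(ages, values, abs_floor=1.0)
        assert not result.smoothed
        assert not result.outlier_flags.any()
        np.testing.assert_array_equal(result.fitted, values)

    def test_noise_free_linear_series_is_identity_with_no_flags(self):
        ages = np.arange(30.0, 80.0, 2.0)
        values = 165.0 - 0.09 * (ages - 40.0)
        result = smooth_with_rejection(ages, values, abs_floor=1.0, frac=0.6)
        assert not result.outlier_flags.any()
        np.testing.assert_allclose(result.fitted, values, atol=1e-8)

    @given(st.integers(0, 500))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_at_least_4_points_always_retained(self, seed):
        """Whenever outliers are flagged, at least 4 points remain for the
        refit (otherwise rejection is abandoned and flags are cleared)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        ages = np.sort(rng.uniform(30.0, 80.0, n))
        while np.any(np.diff(ages) <= 0):
            ages = np.sort(rng.uniform(30.0, 80.0, n))
        values = 170.0 - 0.1 * (ages - 40.0) + rng.normal(0.0, 0.3, n)
        spikes = rng.random(n) < 0.3
        values = values + spikes * rng.choice([-1.0, 1.0], n) * rng.uniform(3, 12, n)
        result = smooth_with_rejection(ages, values, abs_floor=1.0, frac=0.6)
        assert result.smoothed
        assert np.isfinite(result.fitted).all()
        if result.outlier_flags.any():
            assert (~result.outlier_flags).sum() >= 4

    def test_empty_series_is_a_domain_error(self):
        with pytest.raises(DomainError):
            smooth_with_rejection(np.array([]), np.array([]), abs_floor=1.0)


class TestBMIConsistencyFilter:
    def test_large_disagreement_excluded(self):
        # computed BMI = 70/(1.7^2) = 24.22; recorded 30 differs by 5.78
        assert not bmi_consistency_filter(30.0, 70.0, 170.0)

    def test_small_disagreement_kept(self):
        assert bmi_consistency_filter(24.5, 70.0, 170.0)

    def test_exact_agreement_kept(self):
        computed = 70.0 / 1.7**2
        assert bmi_consistency_filter(computed, 70.0, 170.0)

    def test_vectorized(self):
        keep = bmi_consistency_filter(np.array([30.0, 24.5]),
                                      np.array([70.0, 70.0]),
                                      np.array([170.0, 170.0]))
        np.testing.assert_array_equal(keep, [False, True])
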