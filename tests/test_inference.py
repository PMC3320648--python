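"""GLM fitting, ISC, circular-shift nulls and component selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from naturalscan.design import DesignMatrix
from naturalscan.group_ica import ComponentSet, IcaConfig
from naturalscan.inference import (
    IscResult,
    annotation_correlation_matrix,
    circular_null,
    fit_annotation_model,
    isc_mean,
    modality_threshold,
    select_components,
    single_annotation_null,
    single_feature_fits,
    weight_tests,
)


def _design(rng, T=120, k=3):
    return DesignMatrix("custom", [f"x{i}" for i in range(k)],
                        rng.standard_normal((T, k)), 2.0)


class TestFitAnnotationModel:
    def test_exact_regressor_gets_unit_weight_and_r(self, rng):
        X = _design(rng)
        fit = fit_annotation_model(X, X.matrix[:, 1].copy())
        assert fit.normalized_weights[1] == pytest.approx(1.0)
        assert fit.r == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(fit.r**2, abs=1e-12)

    def test_orthogonal_two_regressor_weights(self):
        T = 100
        x1 = np.sin(2 * np.pi * np.arange(T) / 20)
        x2 = np.cos(2 * np.pi * np.arange(T) / 20)  # orthogonal on full periods
        X = DesignMatrix("custom", ["a", "b"], np.column_stack([x1, x2]), 2.0)
        fit = fit_annotation_model(X, 2.0 * x1 + 1.0 * x2)
        np.testing.assert_allclose(fit.normalized_weights, [1.0, 0.5], atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            X = _design(rng, T=80, k=4)
            y = rng.standard_normal(80)
            fit = fit_annotation_model(X, y)
            A = np.column_stack([np.ones(80), X.matrix])
            oracle = np.linalg.solve(A.T @ A, A.T @ y)
            np.testing.assert_allclose(fit.betas, oracle[1:], atol=1e-10)
            np.testing.assert_allclose(fit.intercept, oracle[0], atol=1e-10)

    def test_negative_dominant_weight_is_minus_one(self, rng):
        X = _design(rng)
        y = -3.0 * X.matrix[:, 0] + 0.5 * X.matrix[:, 2]
        fit = fit_annotation_model(X, y)
        assert fit.normalized_weights[0] == pytest.approx(-1.0)
        assert np.all(np.abs(fit.normalized_weights) <= 1.0 + 1e-12)

    def test_collinear_design_names_columns(self, rng):
        M = rng.standard_normal((50, 2))
        M = np.column_stack([M, M[:, 0] + M[:, 1]])
        X = DesignMatrix("custom", ["a", "b", "c"], M, 2.0)
        with pytest.raises(ValueError, match="rank deficient"):
            fit_annotation_model(X, rng.standard_normal(50))


class TestSingleFeatureFits:
    def test_exact_slopes(self, rng):
        x = rng.standard_normal(60)
        Y = np.vstack([3.0 * x, -x])
        np.testing.assert_allclose(single_feature_fits(x, Y), [3.0, -1.0], atol=1e-12)

    def test_sampling_distribution_of_slopes(self, rng):
        x = rng.standard_normal(200)
        true = rng.normal(0.5, 0.1, size=10)
        Y = true[:, None] * x + 0.2 * rng.standard_normal((10, 200))
        betas = single_feature_fits(x, Y)
        se = np.std(betas, ddof=1) / np.sqrt(10)
        assert abs(betas.mean() - 0.5) < 3 * max(se, 0.1 / np.sqrt(10))


class TestWeightTests:
    def test_identical_betas_paired_t_zero_p_one(self, rng):
        b = rng.standard_normal((8, 3))
        out = weight_tests(b, b.copy())
        np.testing.assert_array_equal(out.t_paired, 0.0)
        np.testing.assert_array_equal(out.p_paired, 1.0)

    def test_constant_nonzero_betas_highly_significant(self, rng):
        b = 2.0 + 1e-6 * rng.standard_normal((10, 2))
        out = weight_tests(b, np.zeros((10, 2)) + 1e-6 * rng.standard_normal((10, 2)))
        assert np.all(out.p_c1 < 0.001)

    def test_constant_nonzero_difference_flagged(self):
        b1 = np.tile([1.0, 2.0], (5, 1))
        b2 = np.tile([0.0, 2.0], (5, 1))
        out = weight_tests(b1, b2 + np.random.default_rng(0).normal(0, 0, (5, 2)))
        assert bool(out.degenerate[0])  # constant nonzero difference

    def test_type_one_error_calibrated(self, rng):
        b1 = rng.standard_normal((10, 10_000))
        b2 = rng.standard_normal((10, 10_000))
        out = weight_tests(b1, b2)
        rate = float((out.p_c1 < 0.05).mean())
        assert 0.045 <= rate <= 0.055


class TestIscMean:
    def test_identical_series(self, rng):
        x = rng.standard_normal(100)
        res = isc_mean(np.tile(x, (3, 1)), n_permutations=50)
        assert res.mean_r >= 1 - 1e-6

    def test_equal_pairwise_values_mean_exact(self):
        # Fisher-z mean of identical correlations equals that correlation
        z = np.arctanh(0.2)
        assert np.tanh(np.mean([z, z, z])) == pytest.approx(0.2, abs=1e-15)

    @given(r=st.floats(-0.99, 0.99), n=st.integers(1, 10))
    @settings(derandomize=True, deadline=None)
    def test_fisher_mean_of_identical_correlations_is_identity(self, r, n):
        from naturalscan.inference import _fisher_mean

        assert _fisher_mean(np.full(n, r)) == pytest.approx(r, abs=1e-9)

    def test_fisher_mean_of_mixed_pair(self, rng):
        # construct two pairs with r = 0 and r = 0.8 and check the hand value
        from naturalscan.inference import _fisher_mean

        assert _fisher_mean(np.array([0.0, 0.8])) == pytest.approx(0.5, abs=1e-12)

    def test_planted_isc_significant_noise_not(self, rng):
        shared = rng.standard_normal(150)
        Y = shared + 0.3 * rng.standard_normal((4, 150))
        res = isc_mean(Y, n_permutations=200, seed=1)
        assert res.p_value < 0.01
        noise = rng.standard_normal((4, 150))
        res_n = isc_mean(noise, n_permutations=200, seed=1)
        assert res_n.p_value > 0.05

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError):
            isc_mean(np.ones((1, 50)))

    def test_dispersion_reports_variance_and_sd(self, rng):
        Y = rng.standard_normal((4, 80))
        res = isc_mean(Y, n_permutations=10)
        assert res.dispersion == pytest.approx(res.dispersion_sd**2, abs=1e-12)


class TestCircularNull:
    def test_identity_shift_contains_observed_r(self, rng):
        X = _design(rng, T=80)
        y = rng.standard_normal(80)
        null = circular_null(X, y)
        obs = fit_annotation_model(X, y).r
        assert np.isclose(null.r_samples, obs, atol=1e-12).sum() == 1

    def test_realization_count(self, rng):
        X = _design(rng, T=80)
        Y = rng.standard_normal((3, 80))
        null = circular_null(X, Y)
        assert null.n_realizations == 3 * 80

    def test_probabilities_and_monotonicity(self, rng):
        null = circular_null(_design(rng, T=100), rng.standard_normal((2, 100)))
        assert null.bin_probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        ps = np.linspace(0.01, 0.5, 20)
        ts = [null.threshold_at(p) for p in ps]
        assert np.all(np.diff(ts) <= 1e-12)

    def test_threshold_near_analytic_quantile(self, rng):
        # null of |corr| for white noise: r^2 ~ Beta(1/2, (n-2)/2)
        T = 200
        x = rng.standard_normal((T, 1))
        Y = rng.standard_normal((40, T))
        null = circular_null(DesignMatrix("a", ["x"], x, 2.0), Y)
        q = np.sqrt(stats.beta.ppf(1 - 0.01, 0.5, (T - 2) / 2))
        assert null.threshold_at(0.01) == pytest.approx(q, abs=0.02)

    def test_short_series_warns(self, rng):
        with pytest.warns(UserWarning, match="unstable"):
            circular_null(_design(rng, T=40), rng.standard_normal(40))

    def test_separate_models_give_different_thresholds(self, rng):
        T = 150
        Y = rng.standard_normal((10, T))
        small = circular_null(_design(rng, T=T, k=2), Y)
        big = circular_null(_design(rng, T=T, k=8), Y)
        assert big.threshold_at(0.01) > small.threshold_at(0.01)


class TestSingleAnnotationNull:
    def test_two_step_increment_count(self, rng):
        T = 679
        null = single_annotation_null(rng.standard_normal(T),
                                      rng.standard_normal((1, T)))
        assert null.n_realizations == int(np.ceil(T / 2))

    def test_symmetric_null_median_near_zero(self, rng):
        null = single_annotation_null(rng.standard_normal(400),
                                      rng.standard_normal((5, 400)))
        assert abs(null.threshold_at(0.5)) <= 0.02

    def test_modality_threshold_is_mean(self, rng):
        import dataclasses

        n = single_annotation_null(rng.standard_normal(100),
                                   rng.standard_normal(100))
        nulls = []
        for t in (0.3, 0.4, 0.5):
            # pin each null's threshold by rigging a degenerate bin table
            nulls.append(dataclasses.replace(
                n, bin_centers=np.array([t, t]), bin_probabilities=np.array([0.5, 0.5])))
        assert modality_threshold(nulls, 0.25) == pytest.approx(0.4)


class TestAnnotationCorrelationMatrix:
    def test_symmetric_unit_diagonal(self, rng, small_study):
        R, (counts, edges) = annotation_correlation_matrix(small_study[0])
        M = R.to_numpy()
        np.testing.assert_allclose(M, M.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(M), 1.0)
        assert counts.sum() == M.shape[0] * (M.shape[0] - 1) // 2

    def test_duplicate_track_perfectly_correlated(self, rng):
        x = rng.standard_normal(200)
        R, _ = annotation_correlation_matrix(np.vstack([x, x]))
        assert R.iloc[0, 1] == pytest.approx(1.0)

    def test_independent_tracks_nearly_uncorrelated(self, rng):
        R, _ = annotation_correlation_matrix(rng.standard_normal((2, 2000)))
        assert abs(R.iloc[0, 1]) < 0.1

    def test_constant_track_flagged_nan(self, rng):
        R, _ = annotation_correlation_matrix(np.vstack([np.ones(50),
                                                        rng.standard_normal(50)]))
        assert np.isnan(R.iloc[0, 1]) and R.iloc[0, 0] == 1.0


class TestSelectComponents:
    @staticmethod
    def _setup(stab, isc_p, r_aud, thr=0.4):
        k = len(stab)
        comps = ComponentSet(np.eye(k, 20), np.zeros((k, 10)),
                             np.asarray(stab, float),
                             np.full(k, 10))
        iscs = [IscResult(np.zeros(3), 0.5, 0.0, 0.0, p) for p in isc_p]
        from naturalscan.inference import ModelFit, PermutationNull

        fits = {"auditory": [
            ModelFit(["x"], np.ones(1), 0.0, np.ones(1), np.zeros(10), r, r * r)
            for r in r_aud]}
        null = PermutationNull("auditory", np.array([thr]),
                               np.array([thr, thr + 0.01]), np.array([0.999, 0.001]),
                               1, 1)
        cfg = IcaConfig(n_components=k, n_runs=10)
        return comps, iscs, fits, {"auditory": null}, cfg

    def test_failing_only_stability_excluded(self):
        comps, iscs, fits, nulls, cfg = self._setup([0.85], [1e-5], [0.9])
        assert len(select_components(comps, iscs, fits, nulls, cfg)) == 0

    def test_passing_all_three_included(self):
        comps, iscs, fits, nulls, cfg = self._setup([0.95], [1e-5], [0.9])
        assert list(select_components(comps, iscs, fits, nulls, cfg)) == [0]

    def test_failing_isc_or_model_excluded(self):
        comps, iscs, fits, nulls, cfg = self._setup(
            [0.95, 0.95, 0.95], [1e-5, 0.5, 1e-5], [0.9, 0.9, 0.1])
        assert list(select_components(comps, iscs, fits, nulls, cfg)) == [0]
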