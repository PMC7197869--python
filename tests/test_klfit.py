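"""Unit tests of the KL feature-distribution matching estimator."""

import numpy as np
import pandas as pd
import pytest

from msninfer.features import FEATURE_NAMES
from msninfer.klfit import (
    KLParameterEstimator,
    ModelLibrary,
    eiv_regression,
    fit_dataset,
    kl_distance,
    median_split_joint,
    recovery_experiment,
    recovery_slopes,
    subset_estimate,
)

N_FEAT_TOTAL = len(FEATURE_NAMES)


def gaussian_features(rng, n, shift=0.0):
    return rng.normal(shift, 1.0, size=(n, N_FEAT_TOTAL))


class TestMedianSplitJoint:
    def test_own_medians_single_feature_half_half(self):
        rng = np.random.default_rng(0)
        X = gaussian_features(rng, 1001)
        med = np.median(X, axis=0)
        p = median_split_joint(X, med, np.array([4]))
        assert p.shape == (2,)
        assert p.sum() == pytest.approx(1.0)
        assert p[0] == pytest.approx(0.5, abs=0.01)

    def test_seven_features_gives_128_bins(self):
        rng = np.random.default_rng(1)
        X = gaussian_features(rng, 500)
        p = median_split_joint(X, np.median(X, axis=0), np.arange(7))
        assert p.shape == (128,)
        assert p.sum() == pytest.approx(1.0)

    def test_independent_features_uniform_bins_brute_force(self):
        rng = np.random.default_rng(2)
        X = gaussian_features(rng, 40_000)
        med = np.median(X, axis=0)
        subset = np.array([0, 5, 9])
        p = median_split_joint(X, med, subset)
        # brute-force enumeration oracle
        expected = np.zeros(8)
        for row in X:
            idx = sum((1 << k) for k, j in enumerate(subset) if row[j] > med[j])
            expected[idx] += 1
        expected /= len(X)
        assert p == pytest.approx(expected, abs=1e-12)
        assert np.abs(p - 1 / 8).max() < 0.02

    def test_bit_pattern_indexing(self):
        # one observation above the reference in feature j only -> bin 2^pos
        X = np.zeros((1, N_FEAT_TOTAL))
        X[0, 3] = 5.0
        p = median_split_joint(X, np.zeros(N_FEAT_TOTAL), np.array([1, 3, 6]))
        assert p[2] == 1.0      # bit 1 of (1,3,6) subset

    def test_tie_counts_as_below(self):
        X = np.zeros((4, N_FEAT_TOTAL))
        p = median_split_joint(X, np.zeros(N_FEAT_TOTAL), np.array([0]))
        assert p[0] == 1.0


class TestKLDistance:
    def test_identical_distributions_near_zero(self):
        p = np.array([0.25, 0.75])
        assert abs(kl_distance(p, p)) < 1e-5

    def test_hand_example(self):
        k = kl_distance(np.array([0.75, 0.25]), np.array([0.5, 0.5]))
        expected = 0.75 * np.log(1.5) + 0.25 * np.log(0.5)
        assert k == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(0.1308, abs=5e-4)

    def test_empty_model_bin_stays_finite(self):
        k = kl_distance(np.array([0.5, 0.5]), np.array([1.0, 0.0]))
        assert np.isfinite(k)

    def test_zero_data_bin_contributes_nothing(self):
        assert kl_distance(np.array([1.0, 0.0]), np.array([0.5, 0.5])) == \
            pytest.approx(np.log(2), abs=1e-6)


class TestSubsetEstimate:
    def test_equal_k_gives_unweighted_mean(self):
        est, _ = subset_estimate(np.array([0.3, 0.3, 0.3]),
                                 np.array([[10.0, 1], [20, 2], [30, 3]]))
        assert est[0] == pytest.approx(20.0)
        assert est[1] == pytest.approx(2.0)

    def test_hand_weights(self):
        # K = {1, 2}, beta = 3 -> weights {8/9, 1/9}; x = {10, 20}
        est, spread = subset_estimate(np.array([1.0, 2.0]),
                                      np.array([[10.0], [20.0]]), beta=3.0)
        assert est[0] == pytest.approx(100 / 9)
        expected_sigma = np.sqrt((10 - 100 / 9) ** 2 * 8 / 9
                                 + (20 - 100 / 9) ** 2 / 9)
        assert spread[0] == pytest.approx(expected_sigma)
        assert expected_sigma == pytest.approx(3.14, abs=0.01)

    def test_vanishing_k_concentrates_on_best_model(self):
        est, spread = subset_estimate(np.array([1e-6, 1.0, 1.0]),
                                      np.array([[10.0], [20.0], [30.0]]))
        assert est[0] == pytest.approx(10.0, abs=1e-3)
        assert spread[0] == pytest.approx(0.0, abs=0.1)

    def test_weights_normalized(self):
        k = np.array([0.5, 0.1, 2.0, 0.9])
        logw = -3.0 * np.log(k)
        alpha = np.exp(logw - logw.max())
        alpha /= alpha.sum()
        assert alpha.sum() == pytest.approx(1.0, abs=1e-12)


def make_library(rng, shifts):
    """Models are Gaussian clouds displaced along all features by an amount
    indexed by their (g_e, g_i); closeness in shift = closeness in KL."""
    lib = {}
    for (ge, gi), s in shifts.items():
        lib[(ge, gi)] = gaussian_features(rng, 400, shift=s)
    return lib


class TestFitDataset:
    def setup_method(self):
        self.rng = np.random.default_rng(42)
        self.shifts = {(25.0, 9.0): 0.0, (50.0, 9.0): 0.6, (75.0, 9.0): 1.2,
                       (25.0, 33.0): 1.8, (50.0, 33.0): 2.4, (75.0, 33.0): 3.0}
        self.library = ModelLibrary.from_dict(make_library(self.rng, self.shifts))

    def test_matched_dataset_recovers_its_model(self):
        X = gaussian_features(self.rng, 400, shift=2.4)
        est, grid = fit_dataset(X, self.library, seed=0)
        assert est.g_e == pytest.approx(50.0, abs=13.0)
        assert est.g_i == pytest.approx(33.0, abs=7.0)

    def test_estimate_inside_grid_hull(self):
        X = gaussian_features(self.rng, 300, shift=10.0)   # far outside
        est, _ = fit_dataset(X, self.library, seed=1)
        assert 25.0 <= est.g_e <= 75.0
        assert 9.0 <= est.g_i <= 33.0

    def test_single_subset_equals_subset_estimate(self):
        X = gaussian_features(self.rng, 300, shift=1.0)
        estimator = KLParameterEstimator(self.library, n_subsets=1,
                                         random_state=7).fit(X)
        k = estimator.kl_subsets_[0]
        est, _ = subset_estimate(k, self.library.params)
        assert estimator.g_e_ == pytest.approx(est[0])
        assert estimator.g_i_ == pytest.approx(est[1])

    def test_reproducible_from_seed(self):
        X = gaussian_features(self.rng, 300, shift=1.0)
        a = KLParameterEstimator(self.library, random_state=3).fit(X)
        b = KLParameterEstimator(self.library, random_state=3).fit(X)
        assert a.g_e_ == b.g_e_ and a.g_i_ == b.g_i_
        assert (a.kl_subsets_ == b.kl_subsets_).all()
        assert (a.log_kl_grid_ == b.log_kl_grid_).all()

    def test_subset_weights_normalized(self):
        X = gaussian_features(self.rng, 300, shift=1.0)
        est = KLParameterEstimator(self.library, random_state=5).fit(X)
        assert est.estimate_.subset_weights.sum(axis=0) == pytest.approx(
            [1.0, 1.0], abs=1e-12)

    def test_small_dataset_refused(self):
        X = gaussian_features(self.rng, 5)
        with pytest.raises(ValueError, match="segments"):
            KLParameterEstimator(self.library).fit(X)

    def test_accepts_dataframe(self):
        X = pd.DataFrame(gaussian_features(self.rng, 200, shift=0.6),
                         columns=list(FEATURE_NAMES))
        X["group"] = "wt"
        est, _ = fit_dataset(X, self.library, seed=2)
        assert np.isfinite(est.g_e)


class TestRecoveryExperiment:
    def test_planted_parameters_recovered_on_separable_grid(self):
        rng = np.random.default_rng(3)
        halves = {}
        for i, ge in enumerate([25.0, 50.0, 75.0]):
            for j, gi in enumerate([9.0, 21.0, 33.0]):
                shift = 1.5 * i + 4.5 * j
                halves[(ge, gi)] = (gaussian_features(rng, 300, shift),
                                    gaussian_features(rng, 300, shift))
        table = recovery_experiment(halves, seed=0)
        assert len(table) == 9
        # interior point recovered well; edges pulled inward only
        inner = table[(table.g_e == 50.0) & (table.g_i == 21.0)].iloc[0]
        assert abs(inner.g_i_bias) < 6.0
        assert abs(inner.g_e_bias) < 13.0
        slopes = recovery_slopes(table)
        assert set(slopes.columns) >= {"g_e", "slope", "slope_se", "p_value"}


class TestEIVRegression:
    def test_exact_line_tiny_errors(self):
        x = np.arange(10.0)
        fit = eiv_regression(x, 2 * x + 1, np.full(10, 1e-6), np.full(10, 1e-6))
        assert fit.slope == pytest.approx(2.0, abs=1e-9)
        assert fit.intercept == pytest.approx(1.0, abs=1e-6)
        assert fit.p_value < 1e-10

    def test_reduces_to_wls_when_sx_zero(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 10, 30)
        sy = rng.uniform(0.5, 2.0, 30)
        y = 1.5 * x - 2 + rng.normal(0, sy)
        fit = eiv_regression(x, y, np.zeros(30), sy)
        # WLS oracle
        w = 1 / sy**2
        xb = (w * x).sum() / w.sum()
        yb = (w * y).sum() / w.sum()
        b_wls = (w * (x - xb) * (y - yb)).sum() / (w * (x - xb) ** 2).sum()
        assert fit.slope == pytest.approx(b_wls, rel=1e-9)

    def test_null_p_values_roughly_uniform(self):
        # pure noise: p should not pile up near 0 or 1
        rng = np.random.default_rng(5)
        ps = []
        for k in range(300):
            x = rng.uniform(0, 1, 20)
            y = rng.normal(0, 1, 20)
            ps.append(eiv_regression(x, y, np.full(20, 0.05),
                                     np.full(20, 1.0)).p_value)
        ps = np.asarray(ps)
        from scipy import stats as sps
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_identical_x_singular(self):
        with pytest.raises(ValueError):
            eiv_regression(np.ones(5), np.arange(5.0))
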