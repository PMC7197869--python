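"""Unit tests of the ISI statistics battery against independent oracles."""

import numpy as np
import pytest
from scipy import special, stats as sps

from msninfer.features import (
    CumulativeISI,
    DegenerateTrainError,
    FEATURE_NAMES,
    ISIFeatureExtractor,
    censored_cumulative,
    feature_vector,
    isi_moments,
    ks_distance,
    ks_distances,
    local_cv_quintiles,
    ml_gamma,
    ml_invgauss,
    ml_lognormal,
    serial_autocorrelation,
)
from msninfer.segments import SpikeTrainSegment


def make_segment(isis, t_seg=200.0):
    times = np.concatenate([[0.001], 0.001 + np.cumsum(isis)])
    return SpikeTrainSegment(spike_times=times, t_seg=t_seg)


class TestMoments:
    def test_two_point_isis(self):
        # ISIs {1, 3} repeated: mu = 2, sigma = 1, CV = 0.5
        isis = np.tile([1.0, 3.0], 20)
        mu, cv, _, _ = isi_moments(isis)
        assert mu == pytest.approx(2.0)
        assert cv == pytest.approx(0.5)

    def test_rate_counts_spikes_not_isis(self):
        # 100 spikes in 200 s -> 0.5 Hz regardless of ISI layout
        rng = np.random.default_rng(0)
        isis = rng.exponential(0.3, 99)
        *_, rate = isi_moments(isis, t_seg=200.0)
        assert rate == pytest.approx(0.5)

    def test_constant_isis_degenerate(self):
        with pytest.raises(DegenerateTrainError):
            isi_moments(np.full(20, 0.5))

    def test_skew_matches_scipy_population_skew(self):
        rng = np.random.default_rng(1)
        isis = rng.gamma(2.0, 0.5, 5000)
        _, cv, skew_cv, _ = isi_moments(isis)
        expected = sps.skew(isis, bias=True)
        assert skew_cv * cv == pytest.approx(expected, rel=1e-9)


class TestSerialAutocorrelation:
    def test_iid_isis_near_zero(self):
        rng = np.random.default_rng(2)
        isis = rng.exponential(1.0, 20000)
        assert abs(serial_autocorrelation(isis, 1)) < 0.03
        assert abs(serial_autocorrelation(isis, 2)) < 0.03

    def test_alternating_limit_is_minus_one(self):
        # {a, b, a, b, ...}: rho(1) = (ab - mu^2)/sigma^2 = -1 exactly
        isis = np.tile([0.2, 1.4], 5000)
        assert serial_autocorrelation(isis, 1) == pytest.approx(-1.0, abs=1e-3)

    def test_lag_two_of_alternating_is_positive_one(self):
        isis = np.tile([0.2, 1.4], 5000)
        assert serial_autocorrelation(isis, 2) == pytest.approx(1.0, abs=1e-3)


class TestLocalCV:
    def test_periodic_all_mass_in_first_bin(self):
        lcv = local_cv_quintiles(np.full(50, 0.3))
        assert lcv == pytest.approx([1, 0, 0, 0, 0])

    def test_alternating_three_to_one_hits_middle_bin(self):
        # X = |3b - b|/(3b + b) = 0.5 exactly -> bin 3 with half-open bins
        lcv = local_cv_quintiles(np.tile([0.3, 0.9], 30))
        assert lcv == pytest.approx([0, 0, 1, 0, 0])

    def test_partition_sums_to_one(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            lcv = local_cv_quintiles(rng.lognormal(0, 1.5, 200))
            assert lcv.sum() == pytest.approx(1.0)
            assert (lcv >= 0).all()

    def test_x_equal_one_boundary_in_last_bin(self):
        # only possible in the limit; values just below 1 land in bin 5
        lcv = local_cv_quintiles(np.tile([1e-9, 1.0], 30))
        assert lcv[4] == pytest.approx(1.0)


class TestMLEstimators:
    def test_lognormal_hand_example(self):
        # ISIs {e, e^3}: mu_LN = 2, sigma_LN = 1
        isis = np.tile([np.e, np.e**3], 20)
        mu_ln, sigma_ln = ml_lognormal(isis)
        assert mu_ln == pytest.approx(2.0)
        assert sigma_ln == pytest.approx(1.0)

    def test_lognormal_recovers_planted_parameters(self):
        rng = np.random.default_rng(4)
        n = 100_000
        isis = rng.lognormal(-1.0, 0.8, n)
        mu_ln, sigma_ln = ml_lognormal(isis)
        assert mu_ln == pytest.approx(-1.0, abs=3 * 0.8 / np.sqrt(n))
        assert sigma_ln == pytest.approx(0.8, abs=3 * 0.8 / np.sqrt(2 * n))

    def test_gamma_shape_closed_form_digamma_oracle(self):
        # z = ln(k*s) - (psi(k) + ln s) = ln k - psi(k); for k = 2 the
        # approximation gives 1.992
        z = np.log(2.0) - special.digamma(2.0)
        shape = (3 - z + np.sqrt((3 - z) ** 2 + 24 * z)) / (12 * z)
        assert shape == pytest.approx(1.9922, abs=1e-3)
        rng = np.random.default_rng(5)
        est, scale = ml_gamma(rng.gamma(2.0, 1.0, 100_000))
        assert est == pytest.approx(shape, rel=0.02)

    def test_gamma_exponential_sample_shape_near_one(self):
        rng = np.random.default_rng(6)
        shape, _ = ml_gamma(rng.exponential(1.0, 100_000))
        # analytic z = Euler-Mascheroni gamma -> shape ~ 1.016 in this formula
        assert shape == pytest.approx(1.016, rel=0.02)

    def test_invgauss_hand_example(self):
        # ISIs {0.5, 2}: mu = 1.25, <1/I> = 1.25 -> sigma_IG = 1/0.45
        isis = np.tile([0.5, 2.0], 10)
        assert ml_invgauss(isis) == pytest.approx(1.0 / 0.45)

    def test_invgauss_is_exact_ml_for_lambda(self):
        rng = np.random.default_rng(7)
        n = 100_000
        isis = rng.wald(1.0, 2.0, n)
        # ML lambda-hat has std ~ lambda*sqrt(2/n)
        assert ml_invgauss(isis) == pytest.approx(2.0, abs=3 * 2.0 * np.sqrt(2 / n))

    @pytest.mark.parametrize("fn", [ml_gamma, ml_invgauss])
    def test_constant_data_degenerate(self, fn):
        with pytest.raises(DegenerateTrainError):
            fn(np.full(30, 1.0))


class TestCensoredCumulative:
    def test_normalized_and_monotone(self):
        rng = np.random.default_rng(8)
        cum = censored_cumulative(rng.exponential(0.5, 500), dtau=0.01)
        assert cum.q[0] == pytest.approx(1.0)
        assert (np.diff(cum.q) <= 1e-12).all()

    def test_single_isi_census(self):
        cum = censored_cumulative(np.array([0.015]), dtau=0.01)
        assert cum.q[1] == pytest.approx(1.0)
        assert cum.q[2] == pytest.approx(0.0)

    def test_short_isis_match_uncorrected_survival(self):
        # censorship factor -> 1 when I << T
        rng = np.random.default_rng(9)
        isis = rng.exponential(0.05, 2000)
        cum = censored_cumulative(isis, dtau=0.001, t_seg=200.0)
        grid = np.arange(cum.q.size) * 0.001
        raw = (isis[None, :] >= grid[:, None]).mean(axis=1)
        assert np.abs(cum.q - raw).max() < 0.01

    def test_isi_longer_than_window_rejected(self):
        with pytest.raises(ValueError):
            censored_cumulative(np.array([250.0]), t_seg=200.0)


class TestKSDistance:
    def test_self_distance_below_resolution(self):
        # Q built from the family's own exact CDF on the bin lattice
        dtau = 1e-4
        x = np.arange(1, 60_000) * dtau
        surv = 1.0 - sps.gamma(2.0, scale=0.25).cdf(x)
        q = np.concatenate([[1.0], surv])
        cum = CumulativeISI(q=q, dtau=dtau, t_seg=200.0,
                            support=np.arange(q.size - 1))
        assert ks_distance(cum, "gamma", (2.0, 0.25)) < 1e-3

    def test_sparse_evaluation_equals_brute_force(self):
        rng = np.random.default_rng(10)
        isis = rng.gamma(1.5, 0.4, 300)
        cum = censored_cumulative(isis, dtau=1e-4)
        shape, scale = ml_gamma(isis)
        m = cum.m
        n = np.arange(1, m + 1)
        brute = np.max(np.abs(1.0 - sps.gamma(shape, scale=scale).cdf(n * 1e-4)
                              - cum.q[n]))
        assert ks_distance(cum, "gamma", (shape, scale)) == pytest.approx(brute, abs=1e-12)

    def test_dkw_scaling_for_exponential(self):
        rng = np.random.default_rng(11)
        isis = rng.exponential(0.3, 10_000)
        ks = ks_distances(isis)
        assert ks["ks_e"] < 0.05

    def test_each_family_wins_on_own_data(self):
        rng = np.random.default_rng(12)
        samples = {
            "ks_ln": rng.lognormal(-2.0, 1.5, 500),
            "ks_gamma": rng.gamma(0.7, 0.8, 500),
            "ks_ig": rng.wald(0.8, 2.0, 500),
        }
        for best, sample in samples.items():
            ks = ks_distances(sample[sample < 190])
            two_param = {k: ks[k] for k in ("ks_gamma", "ks_ln", "ks_ig")}
            assert min(two_param, key=two_param.get) == best


class TestFeatureVector:
    def test_length_and_names(self):
        rng = np.random.default_rng(13)
        seg = make_segment(rng.exponential(0.5, 200))
        assert feature_vector(seg).shape == (15,)
        assert len(FEATURE_NAMES) == 15
        assert "lcv3" not in FEATURE_NAMES

    def test_permutation_changes_only_order_statistics(self):
        rng = np.random.default_rng(14)
        isis = rng.lognormal(-1, 1, 300)
        v1 = feature_vector(make_segment(isis))
        v2 = feature_vector(make_segment(rng.permutation(isis)))
        order_free = [i for i, n in enumerate(FEATURE_NAMES)
                      if n in ("mu", "cv", "skew_cv", "rate", "ln_mu_gamma",
                               "sigma_gamma", "mu_ln", "sigma_ln", "sigma_ig")]
        assert v1[order_free] == pytest.approx(v2[order_free])
        assert not np.allclose(v1, v2)       # rho / LCV did change

    def test_deterministic_across_runs(self):
        rng = np.random.default_rng(15)
        isis = rng.exponential(0.4, 100)
        assert (feature_vector(make_segment(isis))
                == feature_vector(make_segment(isis))).all()

    def test_too_few_spikes_rejected(self):
        with pytest.raises(ValueError):
            feature_vector(make_segment(np.full(9, 1.0) + np.arange(9) * 0.01))


class TestExtractor:
    def test_transform_collects_and_logs_rejections(self):
        rng = np.random.default_rng(16)
        good = make_segment(rng.exponential(0.5, 150))
        sparse = make_segment(rng.exponential(0.5, 5))
        periodic = make_segment(np.full(50, 1.0))
        ext = ISIFeatureExtractor().fit([good])
        df = ext.transform([good, sparse, periodic])
        assert len(df) == 1
        assert len(ext.rejections_) == 2
        assert list(df.columns[:15]) == list(FEATURE_NAMES)

    def test_sklearn_get_params_roundtrip(self):
        ext = ISIFeatureExtractor(t_seg=100.0)
        assert ISIFeatureExtractor(**ext.get_params()).t_seg == 100.0
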