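import math

import numpy as np
import pytest
from scipy import stats

from suncache import diststats as ds
from suncache.errors import InsufficientDataError, InvalidInputError

# ---------------------------------------------------------------------------
# dip statistic


def dip_oracle_samples():
    """Deterministic samples whose dip was frozen from the reference R
    implementation (diptest::dip, the implementation the original analysis
    used)."""
    rng = np.random.default_rng(20140401)
    out = []
    for i, n in enumerate([2, 3, 4, 5, 8, 12, 20, 30, 50, 80, 120, 200, 265]):
        kind = i % 3
        if kind == 0:
            x = rng.normal(0.0, 1.0, n)
        elif kind == 1:
            x = rng.uniform(-1.0, 1.0, n)
        else:
            h = n // 2
            x = np.concatenate([rng.normal(-1.01, 0.35, h), rng.normal(0.59, 0.40, n - h)])
        out.append(x)
    return out


# frozen output of R diptest::dip on the samples above, in order
R_DIP_VALUES = [
    0.250000000000000,
    0.166666666666667,
    0.157839787136429,
    0.100000000000000,
    0.127849637194339,
    0.131900656219155,
    0.043665756782427,
    0.065704072330704,
    0.062424538828244,
    0.043307107287701,
    0.023517482514703,
    0.057050328405948,
    0.016492963507806,
]


class TestDipStatistic:
    def test_matches_frozen_reference_values(self):
        for x, expected in zip(dip_oracle_samples(), R_DIP_VALUES):
            assert ds.dip_statistic(x) == pytest.approx(expected, abs=1e-12)

    def test_two_point_sample_quarter(self, rng):
        for _ in range(10):
            x = rng.normal(0, 10, 2)
            assert ds.dip_statistic(x) == pytest.approx(0.25)

    def test_three_point_sample_sixth(self, rng):
        # any 3 distinct points admit the same best unimodal fit error
        for _ in range(10):
            x = rng.normal(0, 1, 3)
            assert ds.dip_statistic(x) == pytest.approx(1 / 6, abs=1e-12)

    def test_lower_bound_half_n(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 200))
            x = rng.normal(0, 1, n)
            assert ds.dip_statistic(x) >= 1 / (2 * n) - 1e-15

    def test_location_scale_invariant(self, rng):
        x = rng.normal(0, 1, 80)
        d = ds.dip_statistic(x)
        assert ds.dip_statistic(3.0 * x - 7.0) == pytest.approx(d, abs=1e-12)

    def test_unimodal_below_critical_bimodal_above(self, rng):
        n = 500
        null = ds.dip_null_distribution(n, 200, rng)
        crit = np.quantile(null, 0.95)
        uni = ds.dip_statistic(rng.normal(0.0, 0.1, n))
        sep = np.concatenate([rng.normal(-3, 1, n // 2), rng.normal(3, 1, n // 2)])
        assert uni < crit
        assert ds.dip_statistic(sep) > crit

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            ds.dip_statistic([1.0])
        with pytest.raises(InsufficientDataError):
            ds.dip_statistic([2.0, 2.0, 2.0])


class TestDipTest:
    def test_requires_n4(self):
        with pytest.raises(InsufficientDataError):
            ds.dip_test([1.0, 2.0, 3.0])

    def test_constant_sample_flagged(self):
        with pytest.raises(InsufficientDataError):
            ds.dip_test([5.0] * 20)

    def test_bimodal_rejects(self, rng):
        x = np.concatenate([rng.normal(-1.01, 0.2, 150), rng.normal(0.59, 0.2, 150)])
        res = ds.dip_test(x, n_mc=500, rng=rng)
        assert res.p < 0.05
        assert res.n_mc == 500

    def test_p_in_unit_interval(self, rng):
        res = ds.dip_test(rng.normal(0, 1, 50), n_mc=200, rng=rng)
        assert 0.0 <= res.p <= 1.0


# ---------------------------------------------------------------------------
# mixture EM


def paper_mixture_sample(rng, n, lam=0.45, mu1=-1.01, mu2=0.59, s1=0.35, s2=0.40):
    k = rng.random(n) < lam
    return np.where(k, rng.normal(mu1, s1, n), rng.normal(mu2, s2, n))


class TestEMFit:
    def test_parameter_recovery_large_n(self, rng):
        x = paper_mixture_sample(rng, 5000, lam=0.5)
        fit = ds.em_fit(x, seed=1, n_starts=5)
        assert fit.converged
        assert fit.mu1 == pytest.approx(-1.01, abs=0.05)
        assert fit.mu2 == pytest.approx(0.59, abs=0.05)
        assert fit.mu1 < fit.mu2

    def test_loglik_matches_reference_implementation(self, rng):
        """Best-of-restarts loglik vs sklearn's EM on 50 datasets: never
        worse than the reference, and equal (1e-6) on nearly all datasets
        (multi-start EM may legitimately find a better optimum the
        reference's initialisation misses)."""
        from sklearn.mixture import GaussianMixture

        n_equal = 0
        for i in range(50):
            n = int(rng.integers(30, 120))
            x = paper_mixture_sample(rng, n)
            fit = ds.em_fit(x, seed=i, n_starts=8)
            gm = GaussianMixture(
                2, n_init=8, tol=1e-10, max_iter=2000, reg_covar=1e-12, random_state=i
            ).fit(x[:, None])
            ref = gm.score(x[:, None]) * n
            assert fit.loglik >= ref - 1e-6
            n_equal += abs(fit.loglik - ref) < 1e-6
        assert n_equal >= 45

    def test_loglik_monotone_nondecreasing(self, rng):
        x = paper_mixture_sample(rng, 300)
        trace = []
        ds._em_once(x, 0.5, -0.5, 0.5, 0.5, 0.5, tol=1e-10, max_iter=500, trace=trace)
        diffs = np.diff(trace)
        assert np.all(diffs >= -1e-9)

    def test_single_gaussian_degenerate_flag(self, rng):
        x = rng.normal(0.2, 0.3, 400)
        fit = ds.em_fit(x, seed=0, n_starts=5)
        assert fit.degenerate  # lambda unidentifiable on one-Gaussian data

    def test_separated_mixture_not_degenerate(self, rng):
        fit = ds.em_fit(paper_mixture_sample(rng, 400), seed=0, n_starts=5)
        assert not fit.degenerate

    def test_needs_ten_points(self):
        with pytest.raises(InsufficientDataError):
            ds.em_fit(np.arange(5, dtype=float))

    def test_label_convention(self, rng):
        for i in range(5):
            x = paper_mixture_sample(rng, 200)
            fit = ds.em_fit(x, seed=i, n_starts=4)
            assert fit.mu1 < fit.mu2
            assert 0 < fit.lam < 1
            assert fit.sigma1 > 0 and fit.sigma2 > 0


class TestBootstrapSE:
    def test_b1_flagged_meaningless(self, rng):
        x = paper_mixture_sample(rng, 200)
        fit = ds.em_fit(x, seed=0, n_starts=4)
        se = ds.bootstrap_se(fit, x, B=1, rng=rng)
        assert se.warning is not None
        assert se.se_mu1 == 0.0

    def test_label_alignment_in_replicates(self, rng):
        x = paper_mixture_sample(rng, 200)
        fit = ds.em_fit(x, seed=0, n_starts=4)
        se = ds.bootstrap_se(fit, x, B=40, rng=rng, return_params=True)
        assert np.all(se.params[:, 1] <= se.params[:, 2])  # mu1 <= mu2 everywhere

    def test_se_scales_inverse_sqrt_n(self, rng):
        ses = []
        for n in (200, 800, 3200):
            x = paper_mixture_sample(rng, n)
            fit = ds.em_fit(x, seed=0, n_starts=4)
            se = ds.bootstrap_se(fit, x, B=60, rng=rng)
            ses.append(se.se_mu2)
        # each 4x increase in n should shrink SE by ~2x (within 40%)
        for a, b in zip(ses, ses[1:]):
            assert 0.3 < (b / a) / 0.5 < 1.7

    def test_se_close_to_single_gaussian_limit(self, rng):
        # well-separated components: se_mu ~ sigma / sqrt(n * weight)
        n = 1000
        k = rng.random(n) < 0.5
        x = np.where(k, rng.normal(-5, 1.0, n), rng.normal(5, 1.0, n))
        fit = ds.em_fit(x, seed=0, n_starts=2)
        se = ds.bootstrap_se(fit, x, B=80, rng=rng)
        limit = 1.0 / math.sqrt(n * 0.5)
        for got in (se.se_mu1, se.se_mu2):
            assert limit / 1.5 < got < limit * 1.5

    def test_unconverged_fit_rejected(self, rng):
        x = paper_mixture_sample(rng, 200)
        fit = ds.em_fit(x, seed=0, n_starts=4)
        bad = ds.MixtureFit(lam=fit.lam, mu1=fit.mu1, mu2=fit.mu2,
                            sigma1=fit.sigma1, sigma2=fit.sigma2,
                            loglik=fit.loglik, n_iter=fit.n_iter,
                            converged=False, n=fit.n)
        with pytest.raises(InvalidInputError):
            ds.bootstrap_se(bad, x, B=5, rng=rng)


# ---------------------------------------------------------------------------
# KS / moments / component comparison


def brute_force_ks(a, b):
    pts = np.concatenate([a, b])
    best = 0.0
    for x in pts:
        fa = np.mean(a <= x)
        fb = np.mean(b <= x)
        best = max(best, abs(fa - fb))
    return best


class TestKS:
    def test_identical_samples_zero(self):
        x = np.arange(10, dtype=float)
        assert ds.ks_2sample(x, x).D == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        assert ds.ks_2sample([1.0, 2.0, 3.0], [10.0, 11.0]).D == pytest.approx(1.0)

    def test_against_brute_force(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, int(rng.integers(5, 40)))
            b = rng.normal(0.5, 1.2, int(rng.integers(5, 40)))
            assert ds.ks_2sample(a, b).D == pytest.approx(brute_force_ks(a, b), abs=1e-12)

    def test_too_small(self):
        with pytest.raises(InsufficientDataError):
            ds.ks_2sample([1.0], [1.0, 2.0])


class TestMoments:
    def test_symmetric_two_point(self):
        m = ds.moments([-1.0, 1.0, -1.0, 1.0])
        assert m["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_uniform_kurtosis(self, rng):
        m = ds.moments(rng.uniform(0, 1, 20000))
        assert m["excess_kurtosis"] == pytest.approx(-1.2, abs=0.05)

    def test_gaussian_near_zero(self, rng):
        m = ds.moments(rng.normal(0, 1, 20000))
        assert abs(m["skewness"]) < 0.06
        assert abs(m["excess_kurtosis"]) < 0.12

    def test_zero_variance_rejected(self):
        with pytest.raises(InvalidInputError):
            ds.moments([2.0] * 10)


class TestCompareComponents:
    def test_mirror_symmetric_components(self, rng):
        n = 2000
        k = rng.random(n) < 0.5
        x = np.where(k, rng.normal(-0.8, 0.3, n), rng.normal(0.8, 0.3, n))
        fit = ds.em_fit(x, seed=0, n_starts=4)
        rep = ds.compare_components(fit, x)
        assert rep["ks_p"] > 0.05
        assert abs(rep["magnitude_diff"]) < 0.05

    def test_paper_structure_left_larger(self, rng):
        x = paper_mixture_sample(rng, 2000)
        fit = ds.em_fit(x, seed=0, n_starts=4)
        rep = ds.compare_components(fit, x)
        assert rep["mean_abs_left"] > rep["mean_abs_right"]
        assert rep["ks_p"] < 0.01  # |-1.01| vs 0.59: clearly different shapes

    def test_component_mean_rejects_zero(self, rng):
        # power check: mu = 0.59 at n = 265 is far from zero
        x = paper_mixture_sample(rng, 265)
        fit = ds.em_fit(x, seed=0, n_starts=4)
        rep = ds.compare_components(fit, x)
        assert rep["p_left"] < 0.001
        assert rep["p_right"] < 0.001

    def test_small_component_raises(self, rng):
        x = np.concatenate([rng.normal(0, 0.1, 100), [5.0, 5.1]])
        fit = ds.MixtureFit(lam=0.98, mu1=0.0, mu2=5.05, sigma1=0.1, sigma2=0.05,
                            loglik=0.0, n_iter=1, converged=True, n=x.size)
        with pytest.raises(InsufficientDataError):
            ds.compare_components(fit, x)


class TestAngleSample:
    def test_bounds_checked(self):
        with pytest.raises(InvalidInputError):
            ds.AngleSample(np.array([0.0, 2.0]))  # 2 rad > pi/2

    def test_n_property(self):
        s = ds.AngleSample(np.array([0.1, -0.2, 0.3]))
        assert s.n == 3
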