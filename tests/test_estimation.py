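"""UMVU estimation of the delta-lognormal mean and its variances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings
from hypothesis import strategies as st
from sklearn.base import clone

from deltalognorm import (
    DeltaLognormalMeanEstimator,
    ModelParams,
    approx_variance_umvue,
    cumulants,
    exact_variance_sample_mean,
    exact_variance_umvue,
    finney_g,
    sample,
    sample_mean_estimate,
    summarize,
    umvue_estimate,
)
from deltalognorm.estimation import _binomial_weights_direct, _log_binomial_weights
from deltalognorm.montecarlo import _replicate_estimates
from deltalognorm.special import DEFAULT_SETTINGS
from tests.conftest import SEED, variance_se

E = math.e


class TestSummarize:
    def test_hand_computed_statistics(self):
        s = summarize([0.0, 0.0, E, E**2])
        assert (s.n, s.n0, s.n1) == (4, 2, 2)
        assert s.ybar_ln == pytest.approx(1.5)
        assert s.s2_ln == pytest.approx(0.5)
        assert s.p0_hat == 0.5

    def test_all_zero_sample(self):
        s = summarize([0.0, 0.0, 0.0])
        assert (s.n, s.n1) == (3, 0)
        assert s.ybar_ln is None and s.s2_ln is None

    def test_singleton_branch(self):
        s = summarize([0.0, 0.0, 0.0, 7.0])
        assert s.n1 == 1 and s.y_singleton == 7.0

    def test_errors(self):
        with pytest.raises(ValueError, match="index 2"):
            summarize([0.0, 1.0, -3.0])
        with pytest.raises(ValueError):
            summarize([])


class TestSampleMean:
    def test_direct_arithmetic(self):
        r = sample_mean_estimate(summarize([0.0, 2.0, 4.0]))
        assert r.kappa1_hat == 2.0
        assert r.kappa2_hat == pytest.approx(4.0)
        assert r.var_hat_kappa1 == pytest.approx(4.0 / 3.0)

    def test_constant_sample(self):
        r = sample_mean_estimate(summarize([3.0, 3.0, 3.0]))
        assert (r.kappa1_hat, r.var_hat_kappa1) == (3.0, 0.0)

    def test_single_observation_flagged(self):
        r = sample_mean_estimate(summarize([5.0]))
        assert r.kappa1_hat == 5.0
        assert math.isnan(r.var_hat_kappa1)

    def test_variance_estimate_recovers_kappa2(self, table1_params):
        # the distribution's fourth moment is enormous at sigma = 2, so the
        # band uses the model-based SE of S^2, not a plug-in estimate
        p = table1_params[0.5]
        n = 10**5
        y = sample(p, n, SEED)
        r = sample_mean_estimate(summarize(y))
        k2 = cumulants(p).kappa2
        m = [(1 - p.p0) * math.exp(k * p.mu + k * k * p.sigma2 / 2) for k in range(5)]
        mu4 = m[4] - 4 * m[3] * m[1] + 6 * m[2] * m[1] ** 2 - 3 * m[1] ** 4
        se_S2 = math.sqrt((mu4 - k2 * k2) / n)
        assert abs(r.var_hat_kappa1 * n - k2) <= 4 * se_S2


class TestUmvue:
    def test_singleton_branches(self):
        r = umvue_estimate(summarize([0.0, 0.0, 0.0, 7.0]))
        assert r.kappa1_hat == pytest.approx(1.75)
        assert r.kappa2_hat == pytest.approx(49.0 / 4.0)
        assert r.var_hat_kappa1 == pytest.approx(3.0625)

    def test_two_positives_closed_form(self):
        # (1 - p0_hat) e^{ybar_ln} 0F1(0.5; s2/8) = 0.5 e^{1.5} cosh(0.5)
        r = umvue_estimate(summarize([0.0, 0.0, E, E**2]))
        assert r.kappa1_hat == pytest.approx(
            0.5 * math.exp(1.5) * math.cosh(0.5), rel=1e-12
        )

    def test_all_zero(self):
        r = umvue_estimate(summarize([0.0, 0.0]))
        assert (r.kappa1_hat, r.kappa2_hat, r.var_hat_kappa1) == (0.0, 0.0, 0.0)

    def test_finney_g_route_agrees(self, rng):
        # the 0F1 form and the g-form of the estimator are the same function
        for p0 in (0.0, 0.3, 0.7):
            y = sample(ModelParams(p0, 1.0, 1.5), 60, rng)
            s = summarize(y)
            if s.n1 < 2:
                continue
            g_form = (
                (1 - s.p0_hat)
                * math.exp(s.ybar_ln)
                * finney_g(s.n1 - 1, s.s2_ln / 2.0)
            )
            r = umvue_estimate(s)
            assert abs(r.kappa1_hat - g_form) <= 1e-10 * max(1.0, g_form)

    def test_unbiasedness_simulation(self, table1_params):
        # E(kappa1_hat) = kappa1 within MC error at the study parameters
        for p0 in (0.1, 0.5, 0.9):
            p = table1_params[p0]
            rng = np.random.default_rng(SEED)
            k1, _ = _replicate_estimates(p, 50, 100_000, rng, DEFAULT_SETTINGS)
            se = k1.std(ddof=1) / math.sqrt(k1.size)
            assert abs(k1.mean() - cumulants(p).kappa1) <= 4 * se

    def test_variance_estimator_unbiasedness(self):
        # E(Vhat(kappa1_hat)) = V(kappa1_hat) within MC error
        p = ModelParams(0.3, 0.0, 1.0)
        rng = np.random.default_rng(SEED + 1)
        K = 30_000
        vh = np.empty(K)
        for i in range(K):
            vh[i] = umvue_estimate(summarize(sample(p, 30, rng))).var_hat_kappa1
        v = exact_variance_umvue(p, 30)
        assert abs(vh.mean() - v) <= 4 * vh.std(ddof=1) / math.sqrt(K)

    def test_variance_estimates_positive_in_practice(self):
        # the 0F1-form unbiased variance estimators are returned as computed
        # (never truncated at zero); empirically they stay positive — the
        # series argument of the subtracted term is always the smaller one
        rng = np.random.default_rng(SEED)
        for _ in range(500):
            y = sample(ModelParams(0.5, 0.0, 2.0), 12, rng)
            r = umvue_estimate(summarize(y))
            if r.kappa2_hat < 0 or r.var_hat_kappa1 < 0:
                assert r.negative_variance_warning
            else:
                assert not r.negative_variance_warning
            assert r.kappa2_hat > 0 or summarize(y).n1 == 0

    @hyp_settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        c=st.floats(0.1, 50.0),
        seed=st.integers(0, 10_000),
    )
    def test_scale_equivariance(self, c, seed):
        y = sample(ModelParams(0.4, 0.5, 1.0), 25, seed)
        base = umvue_estimate(summarize(y))
        scaled = umvue_estimate(summarize(c * y))
        assert scaled.kappa1_hat == pytest.approx(c * base.kappa1_hat, rel=1e-9)
        assert scaled.kappa2_hat == pytest.approx(c**2 * base.kappa2_hat, rel=1e-9)
        assert scaled.var_hat_kappa1 == pytest.approx(
            c**2 * base.var_hat_kappa1, rel=1e-9
        )


class TestExactVariance:
    @pytest.mark.parametrize(
        "p0, n, expected",
        [
            (0.1, 50, 268.1132),
            (0.1, 100, 126.5944),
            (0.5, 50, 167.2448),
            (0.5, 100, 75.8297),
            (0.5, 500, 13.9909),
            (0.5, 1000, 6.9244),
            (0.9, 50, 61.8555),
            (0.9, 1000, 1.4862),
        ],
    )
    def test_reference_values(self, p0, n, expected, table1_params):
        assert exact_variance_umvue(table1_params[p0], n) == pytest.approx(
            expected, abs=5e-5
        )

    def test_monte_carlo_oracle(self):
        p = ModelParams(0.3, 0.0, 0.5)
        rng = np.random.default_rng(SEED)
        k1, _ = _replicate_estimates(p, 40, 200_000, rng, DEFAULT_SETTINGS)
        assert abs(k1.var(ddof=1) - exact_variance_umvue(p, 40)) <= 4 * variance_se(k1)

    def test_log_domain_weights_match_direct_product(self):
        # iterative binomial-coefficient product vs log-gamma route, n <= 60
        for n in (5, 20, 60):
            j = np.arange(2, n + 1)
            for p0 in (0.05, 0.5, 0.9):
                direct = _binomial_weights_direct(n, j, p0)
                viaLog = np.exp(_log_binomial_weights(n, j, p0))
                np.testing.assert_allclose(viaLog, direct, rtol=1e-12)

    def test_pure_lognormal_case(self):
        # p0 = 0: only the j = n binomial term survives (0^0 = 1 convention)
        p = ModelParams(0.0, 0.2, 1.0)
        n = 30
        from deltalognorm import hyp0f1

        expected = math.exp(2 * 0.2 + 1.0) * (
            math.exp(1.0 / n) * hyp0f1((n - 1) / 2, (n - 1) ** 2 / (4 * n * n)) - 1.0
        )
        assert exact_variance_umvue(p, n) == pytest.approx(expected, rel=1e-12)

    def test_large_n_stability(self):
        v = exact_variance_umvue(ModelParams(0.5, 1.5, 4.0), 10_000)
        assert 0 < v < exact_variance_umvue(ModelParams(0.5, 1.5, 4.0), 1000)

    def test_singleton_term_is_small_except_high_p0(self, table1_params):
        lo = exact_variance_umvue(table1_params[0.1], 50)
        hi = exact_variance_umvue(table1_params[0.1], 50, include_singleton_term=True)
        assert hi == pytest.approx(lo, rel=1e-12)
        lo9 = exact_variance_umvue(table1_params[0.9], 50)
        hi9 = exact_variance_umvue(table1_params[0.9], 50, include_singleton_term=True)
        assert hi9 > lo9

    def test_invalid_inputs(self, table1_params):
        with pytest.raises(ValueError):
            exact_variance_umvue(table1_params[0.1], 1)
        with pytest.raises(ValueError):
            exact_variance_umvue(ModelParams(1.0, 0.0, 1.0), 10)


class TestApproxVariance:
    def test_direct_substitution(self):
        # (1/10) * 0.5 * [0.5 + 0.5*1*3] * e = 0.1 e
        assert approx_variance_umvue(ModelParams(0.5, 0.0, 1.0), 10) == pytest.approx(
            0.1 * math.e, rel=1e-14
        )

    def test_vanishes_in_degenerate_limit(self):
        assert approx_variance_umvue(ModelParams(0.0, 0.3, 0.0), 7) == 0.0

    def test_close_to_exact_at_large_n(self, table1_params):
        p = table1_params[0.1]
        ratio = approx_variance_umvue(p, 1000) / exact_variance_umvue(p, 1000)
        assert 0.99 <= ratio <= 1.01

    def test_ratio_improves_with_n(self):
        for p0, sigma in [(0.0, 0.5), (0.5, 1.0), (0.9, 2.0)]:
            p = ModelParams.from_sigma(p0, 0.0, sigma)
            r50 = approx_variance_umvue(p, 50) / exact_variance_umvue(
                p, 50, include_singleton_term=True
            )
            r1000 = approx_variance_umvue(p, 1000) / exact_variance_umvue(
                p, 1000, include_singleton_term=True
            )
            assert abs(r1000 - 1.0) <= abs(r50 - 1.0)


class TestSampleMeanVariance:
    def test_degenerate(self):
        assert exact_variance_sample_mean(ModelParams(1.0, 0.0, 1.0), 5) == 0.0

    def test_substitution(self, table1_params):
        p = table1_params[0.1]
        want = 0.9 * math.exp(7.0) * (math.exp(4.0) - 0.9) / 50.0
        assert exact_variance_sample_mean(p, 50) == pytest.approx(want, rel=1e-12)

    def test_inverse_n_scaling(self, table1_params):
        p = table1_params[0.5]
        assert exact_variance_sample_mean(p, 20) == pytest.approx(
            2 * exact_variance_sample_mean(p, 40), rel=1e-15
        )


class TestSklearnInterface:
    def test_fit_umvu(self):
        est = DeltaLognormalMeanEstimator().fit([0.0, 0.0, 0.0, 7.0])
        assert est.kappa1_ == pytest.approx(1.75)
        assert est.var_kappa1_ == pytest.approx(3.0625)

    def test_fit_sample_mean(self):
        est = DeltaLognormalMeanEstimator(method="sample_mean").fit([0.0, 2.0, 4.0])
        assert est.kappa1_ == 2.0
        assert est.var_kappa1_ == pytest.approx(4.0 / 3.0)

    def test_get_set_params_and_clone(self):
        est = DeltaLognormalMeanEstimator(epsilon=1e-8)
        assert est.get_params()["epsilon"] == 1e-8
        est2 = clone(est).set_params(method="sample_mean")
        assert est2.get_params()["method"] == "sample_mean"

    def test_column_vector_accepted(self):
        est = DeltaLognormalMeanEstimator().fit(np.array([[0.0], [0.0], [7.0], [0.0]]))
        assert est.kappa1_ == pytest.approx(7.0 / 4.0)

    def test_bad_method_raises(self):
        with pytest.raises(ValueError):
            DeltaLognormalMeanEstimator(method="plugin").fit([1.0, 2.0])
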