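"""IVW, MR-Egger, median estimators and heterogeneity diagnostics."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from sexmr.estimators import (
    EggerUnidentifiedError,
    Z975,
    cochran_q,
    egger,
    ivw,
    ratio_estimates,
    simple_median,
    weighted_median,
)
from sexmr.io import HarmonizedInstruments


def make_h(beta_x, se_x, beta_y, se_y):
    k = len(beta_x)
    return HarmonizedInstruments.from_arrays(
        [f"rs{i}" for i in range(k)], beta_x, se_x, beta_y, se_y
    )


def random_h(rng, k=20):
    return make_h(
        rng.normal(0, 0.1, k),
        rng.uniform(0.005, 0.02, k),
        rng.normal(0, 0.05, k),
        rng.uniform(0.01, 0.05, k),
    )


class TestRatioEstimates:
    def test_arithmetic(self):
        h = make_h([0.5], [0.05], [0.25], [0.10])
        res = ratio_estimates(h)
        assert res.ratio[0] == pytest.approx(0.5)
        assert res.se[0] == pytest.approx(0.2)

    def test_zero_outcome_beta(self):
        h = make_h([0.5], [0.05], [0.0], [0.10])
        res = ratio_estimates(h)
        assert res.ratio[0] == 0.0
        assert res.se[0] == pytest.approx(0.2)

    def test_zero_exposure_beta_excluded_with_warning(self):
        h = make_h([0.5, 0.0], [0.05, 0.05], [0.25, 0.1], [0.1, 0.1])
        with pytest.warns(UserWarning, match="beta_x = 0"):
            res = ratio_estimates(h)
        assert res.rsids == ["rs0"]

    def test_delta_method_se_matches_monte_carlo(self, rng):
        # strong instrument (|beta_x/se_x| = 12.5): first-order SE within 10%
        bx, sx, by, sy = 0.5, 0.04, 0.25, 0.1
        draws = rng.normal(by, sy, 100_000) / rng.normal(bx, sx, 100_000)
        delta_se = sy / abs(bx)
        assert np.std(draws) == pytest.approx(delta_se, rel=0.10)


class TestIvw:
    def test_single_snp_equals_wald_ratio(self):
        with pytest.warns(UserWarning, match="fixed-effect"):
            est = ivw(make_h([0.5], [0.05], [0.25], [0.10]))
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.2)
        assert est.or_ == pytest.approx(np.exp(0.5))

    def test_two_snp_closed_form(self):
        est = ivw(make_h([0.1, 0.2], [0.01, 0.01], [0.05, 0.10], [0.01, 0.01]))
        assert est.beta == pytest.approx(0.5, abs=1e-14)
        assert est.q_stat == pytest.approx(0.0, abs=1e-18)
        assert est.se == pytest.approx((1e4 * 0.05) ** -0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_weighted_least_squares_oracle(self, seed):
        rng = np.random.default_rng(seed)
        h = random_h(rng, k=int(rng.integers(3, 40)))
        w = 1.0 / h.se_y**2
        oracle = sm.WLS(h.beta_y, h.beta_x, weights=w).fit().params[0]
        assert abs(ivw(h, model="fixed").beta - oracle) <= 1e-10
        assert abs(ivw(h).beta - oracle) <= 1e-10  # RE shifts only the SE

    def test_random_effects_se_never_below_fixed(self, rng):
        for _ in range(20):
            h = random_h(rng)
            assert ivw(h).se >= ivw(h, model="fixed").se

    def test_ci_is_exp_of_beta_band(self, rng):
        est = ivw(random_h(rng))
        assert est.ci_low == pytest.approx(np.exp(est.beta - Z975 * est.se))
        assert est.ci_high == pytest.approx(np.exp(est.beta + Z975 * est.se))


class TestEgger:
    def test_zero_intercept_instance_matches_ivw_slope(self):
        # y exactly proportional to x: intercept fits 0, slope = IVW slope
        h = make_h([0.1, 0.2, 0.3], [0.01] * 3, [0.05, 0.10, 0.15], [0.02] * 3)
        e = egger(h)
        assert e.egger_intercept == pytest.approx(0.0, abs=1e-14)
        assert e.beta == pytest.approx(ivw(h).beta, abs=1e-12)

    def test_directional_pleiotropy_recovered(self, rng):
        k, slope, intercept = 100, 0.3, 0.1
        x = rng.uniform(0.05, 0.3, k)
        sy = np.full(k, 0.02)
        y = slope * x + intercept + rng.normal(0, sy)
        e = egger(make_h(x, np.full(k, 0.005), y, sy))
        assert abs(e.egger_intercept - intercept) < 3 * e.egger_intercept_se
        assert abs(e.beta - slope) < 3 * e.se

    def test_matches_wls_with_intercept_oracle(self, rng):
        h = random_h(rng)
        sign = np.where(h.beta_x < 0, -1.0, 1.0)
        x, y = h.beta_x * sign, h.beta_y * sign
        fit = sm.WLS(y, sm.add_constant(x), weights=1 / h.se_y**2).fit()
        e = egger(h)
        assert e.egger_intercept == pytest.approx(fit.params[0], abs=1e-12)
        assert e.beta == pytest.approx(fit.params[1], abs=1e-12)

    def test_balanced_pleiotropy_type_i_error(self):
        # zero-mean pleiotropy: the intercept test should reject ~5% of the time
        k, reps = 150, 1000
        rng = np.random.default_rng(42)
        rejections = 0
        for _ in range(reps):
            x = rng.uniform(0.05, 0.3, k)
            sy = np.full(k, 0.01)
            y = 0.3 * x + rng.normal(0, 0.03, k) + rng.normal(0, sy)
            e = egger(make_h(x, np.full(k, 0.005), y, sy))
            rejections += e.egger_intercept_p <= 0.05
        assert 0.035 <= rejections / reps <= 0.065

    def test_no_spread_unidentified(self):
        h = make_h([0.1, 0.1, 0.1], [0.01] * 3, [0.05, 0.06, 0.04], [0.02] * 3)
        with pytest.raises(EggerUnidentifiedError):
            egger(h)

    def test_minimum_three_snps(self):
        with pytest.raises(ValueError, match="at least 3"):
            egger(make_h([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2))


class TestMedians:
    def test_equal_weights_interpolation(self):
        # ratios {0.2, 0.5, 0.9}: cumulative midpoint hits 0.5 exactly at 0.5
        h = make_h([1.0, 1.0, 1.0], [0.01] * 3, [0.2, 0.5, 0.9], [0.1] * 3)
        est = simple_median(h, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.5, abs=1e-12)

    def test_all_weight_on_one_snp(self):
        h = make_h([1.0, 1.0, 1.0], [0.001] * 3, [0.2, 0.7, 0.9], [1e4, 0.001, 1e4])
        est = weighted_median(h, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.7, rel=1e-6)

    def test_simple_equals_weighted_under_equal_ses(self, rng):
        k = 9
        h = make_h(
            np.full(k, 0.2), np.full(k, 0.01), rng.normal(0.1, 0.02, k), np.full(k, 0.03)
        )
        s = simple_median(h, n_boot=500, seed=7)
        w = weighted_median(h, n_boot=500, seed=7)
        assert abs(s.beta - w.beta) <= 1e-12

    def test_bootstrap_deterministic_under_seed(self, rng):
        h = random_h(rng)
        a = weighted_median(h, n_boot=500, seed=11)
        b = weighted_median(h, n_boot=500, seed=11)
        assert (a.beta, a.se) == (b.beta, b.se)
        c = weighted_median(h, n_boot=500, seed=12)
        assert a.se != c.se

    def test_small_bootstrap_warns(self, rng):
        with pytest.warns(UserWarning, match="n_boot"):
            weighted_median(random_h(rng), n_boot=50, seed=1)

    def test_seed_mandatory(self, rng):
        with pytest.raises(ValueError, match="seed"):
            weighted_median(random_h(rng), n_boot=500, seed=None)


class TestCochranQ:
    def test_proportional_data_q_zero(self):
        h = make_h([0.1, 0.2, 0.3], [0.01] * 3, [0.07, 0.14, 0.21], [0.02] * 3)
        q, df, p = cochran_q(h, 0.7)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert (df, p) == (2, 1.0)

    def test_homogeneous_expectation(self):
        # around the fitted slope, homogeneous data give Q ~ chi-square(J-1),
        # so Q/(J-1) has mean 1
        k, reps = 30, 1000
        rng = np.random.default_rng(7)
        vals = []
        for _ in range(reps):
            x = rng.uniform(0.05, 0.3, k)
            sy = rng.uniform(0.01, 0.03, k)
            y = 0.4 * x + rng.normal(0, sy)
            h = make_h(x, np.full(k, 0.005), y, sy)
            q, df, _ = cochran_q(h, ivw(h, model="fixed").beta)
            vals.append(q / df)
        se_mean = np.sqrt(2.0 / (k - 1) / reps)
        assert np.mean(vals) == pytest.approx(1.0, abs=4 * se_mean)

    def test_gross_outlier_inflates_q(self, rng):
        k = 20
        x = rng.uniform(0.05, 0.3, k)
        sy = np.full(k, 0.02)
        y = 0.4 * x
        y[5] += 12 * sy[5]
        q, df, p = cochran_q(make_h(x, np.full(k, 0.005), y, sy), 0.4)
        assert q > sps.chi2.ppf(0.999, df)
        assert p < 1e-3


class TestOrientationInvariance:
    @given(st.integers(0, 2**32 - 1))
    def test_all_estimators_invariant_to_allele_negation(self, seed):
        rng = np.random.default_rng(seed)
        h = random_h(rng, k=12)
        flip = rng.integers(0, 2, 12).astype(bool)
        sgn = np.where(flip, -1.0, 1.0)
        h2 = make_h(h.beta_x * sgn, h.se_x, h.beta_y * sgn, h.se_y)
        for fn in (lambda a: ivw(a), lambda a: egger(a)):
            e1, e2 = fn(h), fn(h2)
            assert e1.beta == pytest.approx(e2.beta, abs=1e-12)
            assert e1.se == pytest.approx(e2.se, abs=1e-12)
        m1 = weighted_median(h, n_boot=200, seed=3)
        m2 = weighted_median(h2, n_boot=200, seed=3)
        assert m1.beta == pytest.approx(m2.beta, abs=1e-12)
        assert m1.se == pytest.approx(m2.se, abs=1e-12)
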