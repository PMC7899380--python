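"""Core distribution functions: cdf/pdf/quantile/sampling and identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, optimize, stats

import bxiime as bx
from bxiime import Params
from bxiime.exceptions import DataValidationError, DomainError

from conftest import PARAM_GRID


def positive_params(draw_scale=True):
    pos = st.floats(0.2, 6.0)
    lam = st.floats(0.1, 10.0) if draw_scale else st.just(1.0)
    return st.tuples(pos, pos, lam).map(lambda t: Params(*t))


class TestParamsAndSample:
    @pytest.mark.parametrize("bad", [(0, 1, 1), (1, -2, 1), (1, 1, float("inf")),
                                     (float("nan"), 1, 1)])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(DomainError):
            Params(*bad)

    def test_sample_container_validates_and_sorts(self):
        s = bx.Sample(np.array([3.0, 1.0, 2.0]))
        assert s.n == 3
        assert np.all(np.diff(s.sorted_values) >= 0)
        assert sorted(s.values.tolist()) == s.sorted_values.tolist()
        with pytest.raises(DataValidationError):
            bx.Sample(np.array([1.0, -1.0]))
        with pytest.raises(DataValidationError):
            bx.Sample(np.array([]))


class TestOdds:
    def test_value_at_one(self):
        # closed form (1 - 2/e) / (2/e)
        expected = (1 - 2 / math.e) / (2 / math.e)
        assert bx.odds_me(1.0, 1.0) == pytest.approx(expected, rel=1e-12)

    def test_zero_and_monotone(self):
        assert bx.odds_me(0.0, 2.0) == 0.0
        grid = np.linspace(0.01, 50, 200)
        w = bx.odds_me(grid, 1.5)
        assert np.all(np.diff(w) > 0)

    def test_small_x_leading_order(self):
        # W ~ (x/lam)^2 / 2 near the origin
        lam = 2.0
        x = 1e-5
        assert bx.odds_me(x, lam) == pytest.approx((x / lam) ** 2 / 2, rel=1e-4)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            bx.odds_me(-1.0, 1.0)
        with pytest.raises(DomainError):
            bx.odds_me(1.0, 0.0)


class TestCdfPdf:
    def test_cdf_at_origin_and_below(self, params):
        assert bx.cdf(0.0, params) == 0.0
        assert bx.cdf(-3.0, params) == 0.0
        assert bx.pdf(-1.0, params) == 0.0

    def test_me_reduction_exact(self):
        # alpha = beta = 1 recovers the moment-exponential cdf
        x = np.linspace(0.01, 20, 50)
        lam = 1.3
        me = -np.expm1(np.log1p(x / lam) - x / lam)
        assert np.allclose(bx.cdf(x, bx.moment_exponential(lam)), me, atol=1e-15)
        assert bx.cdf(1.0, (1, 1, 1)) == pytest.approx(1 - 2 / math.e, abs=1e-15)

    def test_lomax_me_closed_form_survival(self):
        # beta = 1: S(x) = [(1+x/lam) e^{-x/lam}]^alpha
        p = bx.lomax_me(2.7, 1.4)
        x = np.linspace(0.05, 15, 40)
        expected = ((1 + x / p.lam) * np.exp(-x / p.lam)) ** p.alpha
        assert np.allclose(bx.sf(x, p), expected, rtol=1e-12)

    def test_log_logistic_me_closed_form(self):
        # alpha = 1: F = W^beta / (1 + W^beta)
        p = bx.log_logistic_me(2.0, 1.0)
        x = np.linspace(0.1, 10, 30)
        w = bx.odds_me(x, p.lam)
        assert np.allclose(bx.cdf(x, p), w**2 / (1 + w**2), rtol=1e-10)

    def test_pdf_integrates_to_one(self):
        for p in [Params(0.5, 0.5, 1), Params(0.25, 3, 3), Params(5, 2, 0.5)]:
            val, err = integrate.quad(lambda x: bx.pdf(x, p), 0, np.inf, limit=200)
            assert val == pytest.approx(1.0, abs=1e-8)

    def test_pdf_matches_cdf_derivative(self, params):
        x = np.linspace(0.2, 8.0, 25) * params.lam
        h = 1e-6 * params.lam
        numeric = (bx.cdf(x + h, params) - bx.cdf(x - h, params)) / (2 * h)
        assert np.allclose(bx.pdf(x, params), numeric, rtol=1e-6, atol=1e-10)

    def test_small_x_power_law(self):
        # f(x) ~ x^(2*beta - 1): for beta = 2 the density vanishes at 0+
        assert bx.pdf(1e-8, (1.0, 2.0, 1.0)) < 1e-20

    def test_scale_equivariance(self, params):
        c = 3.7
        x = np.linspace(0.1, 12, 30)
        scaled = Params(params.alpha, params.beta, c * params.lam)
        assert np.allclose(bx.cdf(c * x, scaled), bx.cdf(x, params), rtol=1e-12)

    def test_nan_input_rejected(self, params):
        with pytest.raises(DomainError):
            bx.cdf(float("nan"), params)

    def test_no_overflow_far_in_tail(self, params):
        # literal evaluation of the density formula overflows here
        big = 1e4 * params.lam
        assert bx.cdf(big, params) == 1.0
        assert bx.pdf(big, params) == 0.0
        assert np.isfinite(bx.logpdf(big, params))


class TestHazardSuite:
    def test_identities(self, params):
        x = np.linspace(0.1, 10, 40) * params.lam
        hs = bx.hazard_suite(x, params)
        assert np.allclose(hs.sf + bx.cdf(x, params), 1.0, atol=1e-15)
        assert np.allclose(hs.cum_hazard, -np.log(hs.sf), atol=1e-12)
        # hazard via an independent evaluation path
        assert np.allclose(hs.hazard, bx.pdf(x, params) / bx.sf(x, params), rtol=1e-10)
        assert np.allclose(hs.rev_hazard, bx.pdf(x, params) / bx.cdf(x, params),
                           rtol=1e-10)
        assert np.allclose(hs.elasticity, x * hs.rev_hazard, rtol=1e-12)
        for field in hs:
            assert np.all(field >= 0)

    def test_rejects_nonpositive_x(self, params):
        with pytest.raises(DomainError):
            bx.hazard_suite(0.0, params)


class TestQuantile:
    def test_zero_and_domain(self, params):
        assert bx.quantile(0.0, params) == 0.0
        for bad in (-0.1, 1.0, 1.5):
            with pytest.raises(DomainError):
                bx.quantile(bad, params)

    def test_median_against_root_finder(self):
        # independent oracle: beta=1, alpha=0.5 gives T = (0.5^-2 - 1) = 3,
        # so solve (1+u) e^{-u} = 1/4 by Brent's method and scale by lam
        u = optimize.brentq(lambda t: (1 + t) * math.exp(-t) - 0.25, 1, 20,
                            xtol=1e-13)
        expected = 0.5 * u
        assert bx.quantile(0.5, (0.5, 1.0, 0.5)) == pytest.approx(expected, abs=1e-10)
        assert round(expected, 4) == 1.3463

    def test_roundtrip_precision(self, params):
        q = np.arange(0.01, 1.0, 0.01)
        x = bx.quantile(q, params)
        assert np.max(np.abs(bx.cdf(x, params) - q)) < 1e-10

    def test_extreme_tails_still_roundtrip(self, params):
        q = np.array([1e-8, 1e-4, 0.999, 0.999999])
        x = bx.quantile(q, params)
        assert np.allclose(bx.cdf(x, params), q, rtol=1e-6, atol=1e-12)


class TestSampling:
    def test_reproducibility(self, params):
        for method in ("inverse", "gamma_exp"):
            a = bx.sample(100, params, seed=42, method=method)
            b = bx.sample(100, params, seed=42, method=method)
            assert np.array_equal(a.values, b.values)

    def test_methods_agree_in_distribution(self):
        p = Params(0.25, 3, 3)
        a = bx.sample(10_000, p, seed=1, method="inverse")
        b = bx.sample(10_000, p, seed=2, method="gamma_exp")
        assert stats.ks_2samp(a.values, b.values).pvalue > 0.01

    def test_empirical_cdf_within_dkw_band(self):
        p = Params(0.25, 3, 3)
        n = 100_000
        s = bx.sample(n, p, seed=5)
        xs = s.sorted_values
        ecdf_hi = np.arange(1, n + 1) / n
        ecdf_lo = np.arange(0, n) / n
        F = bx.cdf(xs, p)
        sup = max(np.max(np.abs(ecdf_hi - F)), np.max(np.abs(ecdf_lo - F)))
        eps = math.sqrt(math.log(2 / 0.01) / (2 * n))  # 99% DKW band
        assert sup <= eps

    def test_invalid_inputs(self, params):
        with pytest.raises(DomainError):
            bx.sample(0, params, seed=1)
        with pytest.raises(DomainError):
            bx.sample(10, params, seed=1, method="bogus")


class TestPropertyBased:
    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(positive_params(), st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    def test_cdf_monotone(self, p, q1, q2):
        x1, x2 = sorted([q1 * 10, q2 * 10])
        assert bx.cdf(x1, p) <= bx.cdf(x2, p) + 1e-15

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(positive_params(), st.floats(0.001, 0.999))
    def test_quantile_roundtrip(self, p, q):
        assert bx.cdf(bx.quantile(q, p), p) == pytest.approx(q, abs=1e-10)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(positive_params(draw_scale=False), st.floats(0.1, 10),
           st.floats(0.05, 20))
    def test_scale_family(self, p, c, x):
        scaled = Params(p.alpha, p.beta, c * p.lam)
        assert bx.cdf(c * x, scaled) == pytest.approx(bx.cdf(x, p), abs=1e-12)
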