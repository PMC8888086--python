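"""Distributional properties of the power-modified Lindley law.

Every closed form is checked against an independent quadrature oracle or an
exact hand-derived value; the alpha=1 reduction and the power-transform law
pin the family to its modified-Lindley base.
"""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from pmlindley import PML

from conftest import PARAM_GRID, quad_moment

# hand-derived: f(1; a=1, th=1) = 0.5*e^-2*(2e+1), F(1) = 1 - e^-1 - 0.5e^-2
PDF_AT_1 = 0.5 * math.exp(-2.0) * (2.0 * math.e + 1.0)
CDF_AT_1 = 1.0 - math.exp(-1.0) - 0.5 * math.exp(-2.0)


class TestDensity:
    def test_pdf_closed_form_value(self):
        assert PML(1, 1).pdf(1.0) == pytest.approx(PDF_AT_1, rel=1e-12)

    def test_cdf_closed_form_value(self):
        assert PML(1, 1).cdf(1.0) == pytest.approx(CDF_AT_1, rel=1e-12)

    @pytest.mark.parametrize("alpha,theta", PARAM_GRID)
    def test_pdf_integrates_to_one(self, alpha, theta):
        val, _ = integrate.quad(PML(alpha, theta).pdf, 0, np.inf, limit=200)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_alpha_one_reduces_to_modified_lindley(self):
        """With alpha=1 the pdf/cdf equal the base modified-Lindley forms."""
        th = 1.7
        d = PML(1.0, th)
        x = np.linspace(0.05, 6.0, 50)
        g = th / (th + 1) * np.exp(-2 * th * x) * ((1 + th) * np.exp(th * x) + 2 * x * th - 1)
        G = 1 - np.exp(-th * x) * (1 + th * x / (th + 1) * np.exp(-th * x))
        np.testing.assert_allclose(d.pdf(x), g, rtol=1e-12)
        np.testing.assert_allclose(d.cdf(x), G, rtol=1e-12)

    def test_power_transform_law(self):
        """If T ~ PML(1, theta) then T^(1/alpha) ~ PML(alpha, theta)."""
        alpha, th = 2.5, 0.8
        base, powed = PML(1.0, th), PML(alpha, th)
        for p in (0.1, 0.4, 0.75, 0.95):
            assert powed.quantile(p) == pytest.approx(
                base.quantile(p) ** (1 / alpha), rel=1e-8
            )

    def test_logpdf_stable_for_large_argument(self):
        # theta*x^alpha ~ 2000: naive bracket evaluation overflows
        d = PML(2.0, 5.0)
        lp = d.logpdf(20.0)
        assert np.isfinite(lp) and lp < -1000

    def test_cdf_at_zero_and_monotone(self):
        d = PML(2, 1)
        assert d.cdf(0.0) == 0.0
        x = np.linspace(0.0, 10.0, 400)
        assert np.all(np.diff(d.cdf(x)) >= 0)

    def test_cdf_derivative_matches_pdf(self):
        d = PML(1.6, 0.9)
        for x in (0.3, 1.0, 2.5):
            h = 1e-6 * x
            num = (d.cdf(x + h) - d.cdf(x - h)) / (2 * h)
            assert num == pytest.approx(d.pdf(x), rel=1e-6)

    def test_domain_errors(self):
        d = PML(1, 1)
        with pytest.raises(ValueError):
            d.pdf(0.0)
        with pytest.raises(ValueError):
            d.pdf(-1.0)
        with pytest.raises(ValueError):
            d.cdf(-0.1)
        with pytest.raises(ValueError):
            d.hazard(0.0)
        for bad in (0.0, -1.0, np.inf, np.nan):
            with pytest.raises(ValueError):
                PML(bad, 1.0)
            with pytest.raises(ValueError):
                PML(1.0, bad)


class TestHazard:
    def test_hazard_definition(self):
        d = PML(1, 1)
        assert d.hazard(1.0) == pytest.approx(
            PDF_AT_1 / (1 - CDF_AT_1), rel=1e-10
        )

    @pytest.mark.parametrize("alpha,theta", PARAM_GRID)
    def test_hazard_finite_on_grid(self, alpha, theta):
        x = np.geomspace(1e-3, 8.0, 200)
        h = PML(alpha, theta).hazard(x)
        assert np.all(np.isfinite(h)) and np.all(h >= 0)


class TestQuantile:
    def test_round_trips(self):
        d = PML(2.0, 0.5)
        for x in (0.1, 1.0, 5.0):
            assert d.quantile(d.cdf(x)) == pytest.approx(x, rel=1e-8)
        for p in (0.01, 0.5, 0.99):
            assert d.cdf(d.quantile(p)) == pytest.approx(p, abs=1e-10)

    def test_inverse_of_known_cdf_value(self):
        assert PML(1, 1).quantile(CDF_AT_1) == pytest.approx(1.0, rel=1e-9)

    def test_small_p_limit_and_monotonicity(self):
        d = PML(1.5, 2.0)
        ps = np.array([1e-9, 1e-4, 0.1, 0.5, 0.9, 1 - 1e-6])
        qs = d.quantile(ps)
        assert qs[0] < 1e-3
        assert np.all(np.diff(qs) > 0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            PML(1, 1).quantile(0.0)
        with pytest.raises(ValueError):
            PML(1, 1).quantile(1.0)


class TestSampling:
    def test_reproducible(self):
        d = PML(2, 1)
        np.testing.assert_array_equal(d.rvs(100, seed=42), d.rvs(100, seed=42))

    def test_sample_mean_matches_moment(self):
        d = PML(2, 1)
        x = d.rvs(100_000, seed=3)
        mu, m2 = d.moment(1), d.moment(2)
        se = math.sqrt((m2 - mu**2) / x.size)
        assert abs(x.mean() - mu) < 3 * se

    def test_ks_against_cdf(self):
        d = PML(2, 1)
        x = d.rvs(100_000, seed=5)
        stat = stats.kstest(x, d.cdf).statistic
        assert stat < 0.01

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            PML(1, 1).rvs(0)


class TestMoments:
    def test_zeroth_moment_is_one(self):
        assert PML(3, 2).moment(0) == 1.0

    def test_known_values(self):
        # Gamma(2)*(1 + 1/(4*2)) = 1.125 twice over (power-transform identity)
        assert PML(1, 1).moment(1) == pytest.approx(1.125, rel=1e-12)
        assert PML(2, 1).moment(2) == pytest.approx(1.125, rel=1e-12)

    @pytest.mark.parametrize(
        "alpha,theta,r",
        [(1, 1, 1), (2, 1, 2), (0.5, 2, 1.3), (5, 0.3, 2), (2, 0.5, 3.7)],
    )
    def test_against_quadrature(self, alpha, theta, r):
        d = PML(alpha, theta)
        assert d.moment(r) == pytest.approx(quad_moment(d, r), rel=1e-8)

    def test_central_moment_identities(self):
        d = PML(2, 0.7)
        assert d.central_moment(1) == pytest.approx(0.0, abs=1e-12)
        assert d.central_moment(2) == pytest.approx(
            d.moment(2) - d.moment(1) ** 2, abs=1e-12
        )

    def test_skewness_kurtosis_match_quadrature(self):
        d = PML(2, 1)
        mu = d.mean
        m2 = quad_moment(d, 2) - mu**2
        m3 = integrate.quad(lambda x: (x - mu) ** 3 * d.pdf(x), 0, np.inf)[0]
        m4 = integrate.quad(lambda x: (x - mu) ** 4 * d.pdf(x), 0, np.inf)[0]
        assert d.skewness == pytest.approx(m3 / m2**1.5, rel=1e-7)
        assert d.kurtosis == pytest.approx(m4 / m2**2, rel=1e-7)


class TestMGF:
    def test_at_zero(self):
        assert PML(2, 1).mgf(0.0) == 1.0

    def test_matches_quadrature_and_series(self):
        d = PML(2, 1)
        val = d.mgf(0.3)
        oracle = integrate.quad(lambda x: math.exp(0.3 * x) * d.pdf(x), 0, np.inf)[0]
        assert val == pytest.approx(oracle, rel=1e-6)
        assert val == pytest.approx(d.mgf_series(0.3), rel=1e-6)

    def test_divergent_arguments_rejected(self):
        with pytest.raises(ValueError):
            PML(0.5, 1).mgf(0.1)  # subexponential tail
        with pytest.raises(ValueError):
            PML(1, 1).mgf(1.0)  # t >= theta at alpha=1

    def test_negative_t_allowed_for_heavy_shape(self):
        assert 0 < PML(0.5, 1).mgf(-0.5) < 1


class TestIncompleteMoments:
    def test_t_zero_recovers_full_moment(self):
        d = PML(2, 0.5)
        assert d.upper_incomplete_moment(1.5, 0.0) == pytest.approx(
            d.moment(1.5), rel=1e-12
        )

    @pytest.mark.parametrize(
        "alpha,theta,s,t", [(1, 1, 1, 1), (2, 0.5, 1, 1), (2, 1, 2.5, 0.7)]
    )
    def test_against_quadrature(self, alpha, theta, s, t):
        d = PML(alpha, theta)
        assert d.upper_incomplete_moment(s, t) == pytest.approx(
            quad_moment(d, s, lo=t), rel=1e-8
        )
        assert d.lower_incomplete_moment(s, t) == pytest.approx(
            quad_moment(d, s, hi=t), rel=1e-8
        )

    def test_additivity(self):
        d = PML(1.3, 2.0)
        s, t = 1.7, 0.9
        total = d.upper_incomplete_moment(s, t) + d.lower_incomplete_moment(s, t)
        assert total == pytest.approx(d.moment(s), rel=1e-10)

    def test_upper_monotone_nonincreasing_in_t(self):
        d = PML(2, 1)
        vals = [d.upper_incomplete_moment(1, t) for t in np.linspace(0, 3, 20)]
        assert np.all(np.diff(vals) <= 1e-14)

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            PML(1, 1).upper_incomplete_moment(0.0, 1.0)


class TestLifetimeSummaries:
    def test_mrl_at_zero_is_mean(self):
        d = PML(1, 1)
        assert d.mean_residual_life(0.0) == pytest.approx(d.mean, rel=1e-12)

    def test_mrl_against_conditional_quadrature(self):
        d, t = PML(1, 1), 1.0
        oracle = quad_moment(d, 1, lo=t) / d.sf(t) - t
        assert d.mean_residual_life(t) == pytest.approx(oracle, rel=1e-8)

    def test_mrl_nonnegative_on_grid(self):
        d = PML(2, 1)
        for t in np.linspace(0.0, 4.0, 30):
            assert d.mean_residual_life(t) >= -1e-12

    def test_mit_against_conditional_quadrature(self):
        d, t = PML(1, 1), 2.0
        oracle = t - quad_moment(d, 1, hi=t) / d.cdf(t)
        assert d.mean_inactivity_time(t) == pytest.approx(oracle, rel=1e-8)

    def test_mit_bounds(self):
        d = PML(2, 1)
        for t in np.linspace(0.05, 4.0, 25):
            assert 0.0 <= d.mean_inactivity_time(t) <= t
        assert d.mean_inactivity_time(1e-3) < 1e-3

    def test_mean_deviation_about_mean(self):
        d = PML(2, 1)
        mu = d.mean
        oracle = integrate.quad(lambda x: abs(x - mu) * d.pdf(x), 0, np.inf)[0]
        assert d.mean_deviation("mean") == pytest.approx(oracle, rel=1e-7)

    def test_mean_deviation_about_median(self):
        d = PML(2, 1)
        M = d.median
        oracle = (
            integrate.quad(lambda x: (M - x) * d.pdf(x), 0, M)[0]
            + integrate.quad(lambda x: (x - M) * d.pdf(x), M, np.inf)[0]
        )
        assert d.mean_deviation("median") == pytest.approx(oracle, rel=1e-7)

    def test_median_minimises_mean_absolute_deviation(self):
        d = PML(2, 1)
        assert d.mean_deviation("median") <= d.mean_deviation("mean") + 1e-12


class TestInequalityCurves:
    def test_lorenz_is_p_times_bonferroni(self):
        d = PML(2, 1)
        for p in (0.1, 0.35, 0.6, 0.9):
            assert d.lorenz_curve(p) == pytest.approx(
                p * d.bonferroni_curve(p), abs=1e-12
            )

    def test_lorenz_against_quadrature(self):
        d, p = PML(2, 1), 0.5
        q = d.quantile(p)
        oracle = quad_moment(d, 1, hi=q) / d.mean
        assert d.lorenz_curve(p) == pytest.approx(oracle, rel=1e-8)

    def test_lorenz_shape(self):
        d = PML(2, 1)
        ps = np.linspace(0.02, 0.999, 60)
        L = np.array([d.lorenz_curve(p) for p in ps])
        assert np.all(np.diff(L) > 0)  # increasing
        assert np.all(L <= ps + 1e-12)  # below the diagonal
        assert np.all(np.diff(L, 2) > -1e-9)  # convex
        assert d.lorenz_curve(1.0 - 1e-9) == pytest.approx(1.0, abs=1e-6)

    def test_domain(self):
        with pytest.raises(ValueError):
            PML(1, 1).bonferroni_curve(0.0)


class TestResidualLifeMoments:
    def test_order_one_reduces_to_mrl_and_mit(self):
        d, t = PML(1.5, 1.0), 0.8
        assert d.residual_life_moment(1, t) == pytest.approx(
            d.mean_residual_life(t), rel=1e-10
        )
        assert d.reversed_residual_life_moment(1, t) == pytest.approx(
            d.mean_inactivity_time(t), rel=1e-10
        )

    def test_second_order_against_quadrature(self):
        d, t = PML(1, 1), 1.0
        oracle_up = (
            integrate.quad(lambda x: (x - t) ** 2 * d.pdf(x), t, np.inf)[0] / d.sf(t)
        )
        oracle_dn = (
            integrate.quad(lambda x: (t - x) ** 2 * d.pdf(x), 0, t)[0] / d.cdf(t)
        )
        assert d.residual_life_moment(2, t) == pytest.approx(oracle_up, rel=1e-7)
        assert d.reversed_residual_life_moment(2, t) == pytest.approx(
            oracle_dn, rel=1e-7
        )
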