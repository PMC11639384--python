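"""Moments, reliability, inequality, entropy and risk measures."""

import numpy as np
import pytest
from scipy import integrate

from conftest import quad_moment, quad_tail_survival
from ntpqed.distribution import Params, pdf, quantile, sf
from ntpqed.measures import (
    FuzzySpec,
    bonferroni,
    fuzzy_reliability,
    incomplete_moment,
    likelihood_ratio_monotone,
    limited_expected_value,
    lorenz,
    lr_order_holds,
    mean_excess,
    mean_residual_life,
    mean_waiting_time,
    mgf,
    raw_moment,
    renyi_entropy,
    risk_report,
    summary_stats,
    tail_variance,
    tvar,
)


class TestMoments:
    @pytest.mark.parametrize("r", [0, 1, 2, 3, 4])
    def test_raw_moment_vs_quadrature(self, p_any, r):
        assert raw_moment(r, p_any) == pytest.approx(
            quad_moment(r, p_any), rel=1e-9)

    def test_summary_consistency(self, p_any):
        ms = summary_stats(p_any)
        assert ms.mean == pytest.approx(raw_moment(1, p_any), rel=1e-12)
        assert ms.variance == pytest.approx(
            raw_moment(2, p_any) - ms.mean**2, rel=1e-10)
        assert ms.sd == pytest.approx(np.sqrt(ms.variance))
        assert ms.cv == pytest.approx(ms.sd / ms.mean)
        # labelled variants differ in general
        mu = ms.mean
        m2, m3 = raw_moment(2, p_any), raw_moment(3, p_any)
        mu3 = m3 - 3 * mu * m2 + 2 * mu**3
        assert ms.skewness_std == pytest.approx(mu3 / ms.sd**3, rel=1e-8)
        assert ms.skewness_paper == pytest.approx(m3 / ms.variance**1.5, rel=1e-10)

    def test_negative_order_rejected(self, p_ref):
        with pytest.raises(ValueError):
            raw_moment(-1, p_ref)


class TestMgf:
    def test_vs_quadrature(self, p_any):
        s = 0.25 * p_any.beta
        a, b, C = p_any.alpha, p_any.beta, p_any.C
        # overflow-safe integrand: combine both exponentials first
        val, _ = integrate.quad(
            lambda x: C * (a + b * x + x * x) * np.exp((s - b) * x),
            0, np.inf, limit=300)
        assert mgf(s, p_any) == pytest.approx(val, rel=1e-7)

    def test_at_zero_is_one(self, p_any):
        assert mgf(0.0, p_any) == pytest.approx(1.0, rel=1e-12)

    def test_domain(self, p_ref):
        with pytest.raises(ValueError):
            mgf(p_ref.beta, p_ref)


class TestIncompleteMoments:
    @pytest.mark.parametrize("r", [1, 2])
    def test_vs_quadrature(self, p_any, r):
        mean = summary_stats(p_any).mean
        for s in (0.3 * mean, mean, 4 * mean):
            assert incomplete_moment(r, s, p_any) == pytest.approx(
                quad_moment(r, p_any, upper=s), rel=1e-8, abs=1e-12)

    def test_limits(self, p_ref):
        assert incomplete_moment(1, 0.0, p_ref) == 0.0
        assert incomplete_moment(1, 1e3, p_ref) == pytest.approx(
            summary_stats(p_ref).mean, rel=1e-10)


class TestResidualLife:
    def test_mrl_matches_integral_definition(self, p_any):
        mean = summary_stats(p_any).mean
        for t in (0.5 * mean, 1.5 * mean):
            expect = quad_tail_survival(t, p_any) / sf(t, p_any)
            assert mean_residual_life(t, p_any) == pytest.approx(expect, rel=1e-7)

    def test_mwt_positive_below_t(self, p_any):
        mean = summary_stats(p_any).mean
        w = mean_waiting_time(mean, p_any)
        assert 0 < w < mean


class TestInequalityCurves:
    def test_lorenz_below_diagonal_and_convex(self, p_any):
        u = np.linspace(0.05, 0.95, 19)
        L = np.array([lorenz(v, p_any) for v in u])
        assert np.all(L <= u + 1e-12)
        assert np.all(np.diff(L, 2) >= -1e-9)  # discrete convexity

    def test_bonferroni_is_lorenz_over_u(self, p_ref):
        for u in (0.2, 0.5, 0.8):
            assert bonferroni(u, p_ref) == pytest.approx(
                lorenz(u, p_ref) / u, rel=1e-12)


class TestRenyi:
    @pytest.mark.parametrize("s", [2, 3])
    def test_series_matches_quadrature(self, p_any, s):
        a = renyi_entropy(s, p_any, method="series")
        b = renyi_entropy(s, p_any, method="quadrature")
        assert a == pytest.approx(b, rel=1e-9, abs=1e-9)

    def test_noninteger_order(self, p_ref):
        val = renyi_entropy(1.7, p_ref)
        assert np.isfinite(val)

    def test_invalid_orders(self, p_ref):
        for s in (1, 0, -2):
            with pytest.raises(ValueError):
                renyi_entropy(s, p_ref)


class TestFuzzyReliability:
    def test_bounds(self, p_any):
        spec = FuzzySpec(0.5, 2.0, 0.6)
        r = fuzzy_reliability(spec, p_any)
        assert 0.0 <= r <= sf(0.5, p_any)

    def test_monotone_in_lambda_and_t2_antitone_in_t1(self, p_any):
        lams = [fuzzy_reliability(FuzzySpec(0.5, 2.0, lam), p_any)
                for lam in np.linspace(0, 1, 6)]
        assert np.all(np.diff(lams) >= 0)
        t2s = [fuzzy_reliability(FuzzySpec(0.5, t2, 0.7), p_any)
               for t2 in (1.0, 2.0, 4.0)]
        assert np.all(np.diff(t2s) >= 0)
        # antitone in t1 on the decreasing stretch of the density (beyond any
        # mode); on a rising stretch the inequality can legitimately reverse
        from ntpqed.distribution import pdf_shape
        base = pdf_shape(p_any).mode
        t2 = base + 10.0 / p_any.beta
        t1s = [fuzzy_reliability(FuzzySpec(base + d / p_any.beta, t2, 0.7), p_any)
               for d in (0.2, 0.8, 2.0)]
        assert np.all(np.diff(t1s) <= 1e-12)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            FuzzySpec(2.0, 1.0, 0.5)
        with pytest.raises(ValueError):
            FuzzySpec(0.0, 1.0, 1.5)


class TestMeanExcess:
    def test_integral_form_vs_oracle(self, p_any):
        for x in (0.5, 2.0):
            expect = quad_tail_survival(x, p_any) / sf(x, p_any)
            assert mean_excess(x, p_any, form="integral") == pytest.approx(
                expect, rel=1e-7)

    def test_forms_disagree_for_large_threshold(self, p_ref):
        # the product formula grows polynomially; the integral tends to 1/beta
        # (O(1/(beta x)) corrections remain at this threshold)
        x = 15.0 / p_ref.beta
        integral = mean_excess(x, p_ref, form="integral")
        assert integral == pytest.approx(1 / p_ref.beta, rel=0.2)
        assert mean_excess(x, p_ref, form="paper") > 10 * integral

    def test_form_is_mandatory(self, p_ref):
        with pytest.raises(TypeError):
            mean_excess(1.0, p_ref)  # noqa: missing form on purpose
        with pytest.raises(ValueError):
            mean_excess(1.0, p_ref, form="other")


class TestRisk:
    def test_limited_ev_identity(self, p_any):
        # E(X ∧ u) = T1(u) + u S(u); layer decomposition with the tail
        mean = summary_stats(p_any).mean
        for u in (0.5 * mean, 2 * mean):
            lev = limited_expected_value(u, p_any)
            assert lev == pytest.approx(
                incomplete_moment(1, u, p_any) + u * sf(u, p_any), rel=1e-10)
            assert lev + quad_tail_survival(u, p_any) == pytest.approx(
                mean, rel=1e-8)

    def test_limited_ev_vs_quadrature(self, p_any):
        mean = summary_stats(p_any).mean
        u = 0.8 * mean
        direct, _ = integrate.quad(
            lambda x: min(x, u) * pdf(x, p_any), 0, np.inf, limit=300)
        assert limited_expected_value(u, p_any) == pytest.approx(direct, rel=1e-7)

    def test_tvar_identity_and_quadrature(self, p_any):
        level = 0.9
        v = quantile(level, p_any)
        mean = summary_stats(p_any).mean
        t = tvar(level, p_any)
        # TVaR(p)(1-p) + T1(VaR) = E[X]
        assert t * (1 - level) + incomplete_moment(1, v, p_any) == pytest.approx(
            mean, rel=1e-9)
        direct, _ = integrate.quad(lambda x: x * pdf(x, p_any), v, np.inf,
                                   limit=300)
        assert t == pytest.approx(direct / (1 - level), rel=1e-7)

    def test_tail_variance_vs_quadrature(self, p_any):
        level = 0.9
        v = quantile(level, p_any)
        e2, _ = integrate.quad(lambda x: x * x * pdf(x, p_any), v, np.inf,
                               limit=300)
        expect = e2 / (1 - level) - tvar(level, p_any) ** 2
        assert tail_variance(level, p_any) == pytest.approx(
            expect, rel=1e-6, abs=1e-10)

    def test_risk_report_bundle(self, p_ref):
        rep = risk_report(0.95, p_ref)
        assert rep.var_p == pytest.approx(quantile(0.95, p_ref))
        assert rep.tvar_p > rep.var_p
        assert rep.tv_p > 0
        assert rep.limited_ev_at_var < summary_stats(p_ref).mean


class TestStochasticOrder:
    def test_sufficient_conditions_imply_monotone_ratio(self):
        p1, p2 = Params(2.0, 2.0), Params(1.0, 1.0)
        assert lr_order_holds(p1, p2)
        assert likelihood_ratio_monotone(p1, p2)

    def test_violated_conditions(self):
        p1, p2 = Params(1.0, 1.0), Params(2.0, 2.0)
        assert not lr_order_holds(p1, p2)
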