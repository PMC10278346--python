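"""Parametric survival fitting, selection and transition probabilities."""

import math
import warnings

import numpy as np
import pytest
from scipy import optimize

import tkicea as tk
from tkicea.survival import (
    NoEventsError,
    SelectionImpossibleError,
    UnsupportedFamilyError,
    _logpdf,
    _logsf,
    _neg_loglik,
)


class TestExponentialMLE:
    def test_closed_form_on_uncensored_sample(self):
        data = (np.array([1.0, 2.0, 3.0, 4.0]), np.array([1, 1, 1, 1]))
        m = tk.fit_parametric(data, "exponential")
        assert m.params[0] == pytest.approx(0.4, rel=1e-12)  # 4 events / 10 years
        assert m.aic == pytest.approx(2 - 2 * m.loglik)
        assert m.bic == pytest.approx(math.log(4) - 2 * m.loglik)

    def test_closed_form_agrees_with_numerical_optimum(self):
        """Independent 1-D numerical maximization lands on events/Σt."""
        ipd = tk.simulate_ipd("exponential", (0.3,), n=300, censor_rate=0.1, seed=6)
        m = tk.fit_parametric(ipd, "exponential")
        res = optimize.minimize_scalar(
            lambda lam: _neg_loglik("exponential", np.array([lam]), ipd.time, ipd.event),
            bounds=(1e-6, 5.0),
            method="bounded",
        )
        assert m.params[0] == pytest.approx(res.x, rel=1e-6)

    def test_parameter_recovery_with_censoring(self):
        ipd = tk.simulate_ipd("exponential", (0.1788,), n=1000, censor_rate=0.02, seed=11)
        m = tk.fit_parametric(ipd, "exponential")
        assert abs(m.params[0] - 0.1788) / 0.1788 < 0.10

    def test_all_censored_raises(self):
        with pytest.raises(NoEventsError):
            tk.fit_parametric((np.array([1.0, 2.0]), np.array([0, 0])), "exponential")


@pytest.fixture(scope="module")
def exp_data():
    return tk.simulate_ipd("exponential", (0.1788,), n=1000, censor_rate=0.02, seed=11)


@pytest.fixture(scope="module")
def weibull_data():
    return tk.simulate_ipd("weibull", (1.4, 5.0), n=400, censor_rate=0.05, seed=13)


class TestNestedFamilies:
    def test_weibull_contains_exponential(self, exp_data):
        m_exp = tk.fit_parametric(exp_data, "exponential")
        m_wb = tk.fit_parametric(exp_data, "weibull")
        assert 0.85 <= m_wb.params[0] <= 1.15  # shape near 1 on exponential data
        assert m_wb.loglik >= m_exp.loglik - 1e-6
        assert m_wb.aic >= m_exp.aic - 2.0

    def test_gamma_shape_one_is_exponential(self):
        m_exp = tk.SurvivalModel("exponential", (0.25,))
        m_gam = tk.SurvivalModel("gamma", (1.0, 0.25))
        t = np.linspace(0, 20, 50)
        assert np.allclose(m_exp.survival(t), m_gam.survival(t), atol=1e-12)

    def test_gompertz_zero_shape_is_exponential(self):
        m_exp = tk.SurvivalModel("exponential", (0.25,))
        m_gom = tk.SurvivalModel("gompertz", (0.0, 0.25))
        t = np.linspace(0, 20, 50)
        assert np.allclose(m_exp.survival(t), m_gom.survival(t), atol=1e-12)

    def test_generalized_gamma_limits(self):
        t = np.linspace(0.01, 20, 50)
        # Q → 0 limit is log-normal
        m_ln = tk.SurvivalModel("log-normal", (1.0, 0.7))
        m_gg0 = tk.SurvivalModel("generalized-gamma", (1.0, 0.7, 0.0))
        assert np.allclose(m_ln.survival(t), m_gg0.survival(t), atol=1e-10)
        # Q = 1 is Weibull with shape 1/σ, scale exp(μ)
        m_wb = tk.SurvivalModel("weibull", (1 / 0.7, math.exp(1.0)))
        m_gg1 = tk.SurvivalModel("generalized-gamma", (1.0, 0.7, 1.0))
        assert np.allclose(m_wb.survival(t), m_gg1.survival(t), atol=1e-10)


class TestAgainstLifelines:
    """lifelines' univariate fitters are the independent MLE oracle."""

    @pytest.mark.parametrize(
        "family,fitter,extract",
        [
            ("weibull", "WeibullFitter", lambda f: (f.rho_, f.lambda_)),
            ("log-normal", "LogNormalFitter", lambda f: (f.mu_, f.sigma_)),
            ("log-logistic", "LogLogisticFitter", lambda f: (f.beta_, f.alpha_)),
        ],
    )
    def test_params_and_loglik_match(self, weibull_data, family, fitter, extract):
        import lifelines

        m = tk.fit_parametric(weibull_data, family)
        lf = getattr(lifelines, fitter)().fit(weibull_data.time, weibull_data.event)
        assert np.allclose(m.params, extract(lf), rtol=1e-3)
        assert m.loglik == pytest.approx(lf.log_likelihood_, rel=1e-6)

    def test_exponential_rate_matches(self, weibull_data):
        from lifelines import ExponentialFitter

        m = tk.fit_parametric(weibull_data, "exponential")
        lf = ExponentialFitter().fit(weibull_data.time, weibull_data.event)
        assert m.params[0] == pytest.approx(1.0 / lf.lambda_, rel=1e-6)


class TestSurvivalEvaluation:
    def test_calibrated_landmarks(self):
        assert tk.survival_at(tk.SurvivalModel("exponential", (0.17884,)), 4.0) == (
            pytest.approx(0.489, abs=5e-4)
        )
        assert tk.survival_at(tk.SurvivalModel("exponential", (0.0308,)), 4.0) == (
            pytest.approx(0.884, abs=5e-4)
        )

    @pytest.mark.parametrize(
        "family,params",
        [
            ("exponential", (0.2,)),
            ("weibull", (1.5, 3.0)),
            ("gamma", (2.0, 0.5)),
            ("generalized-gamma", (1.0, 0.7, 0.5)),
            ("gompertz", (0.1, 0.2)),
            ("log-logistic", (2.0, 3.0)),
            ("log-normal", (1.0, 0.6)),
        ],
    )
    def test_survivor_function_shape(self, family, params):
        m = tk.SurvivalModel(family, params)
        assert m.survival(0.0) == 1.0
        t = np.linspace(0.0, 30.0, 200)
        s = m.survival(t)
        assert np.all(np.diff(s) <= 1e-12)
        assert np.all((0.0 <= s) & (s <= 1.0))
        with pytest.raises(ValueError):
            m.survival(-1.0)

    def test_transition_probability_memoryless(self):
        m = tk.SurvivalModel("exponential", (0.17884,))
        p0 = tk.cycle_transition_prob(m, 0.0, 0.25)
        p5 = tk.cycle_transition_prob(m, 5.0, 0.25)
        assert p0 == pytest.approx(1 - math.exp(-0.17884 * 0.25), rel=1e-12)
        assert p0 == pytest.approx(0.04373, abs=5e-5)
        assert p0 == pytest.approx(p5, rel=1e-12)

    def test_transition_probability_limits_and_hazard(self):
        m = tk.SurvivalModel("weibull", (2.0, 1.0))
        assert tk.cycle_transition_prob(m, 0.0, 1e-9) < 1e-6
        # increasing hazard: later cycles carry higher event probability
        assert tk.cycle_transition_prob(m, 1.0, 0.25) > tk.cycle_transition_prob(m, 0.0, 0.25)
        # grid sanity across families
        for fam, par in [("gompertz", (0.3, 0.1)), ("log-normal", (0.5, 0.8))]:
            mm = tk.SurvivalModel(fam, par)
            for t in (0.0, 0.5, 2.0, 10.0):
                p = tk.cycle_transition_prob(mm, t, 0.25)
                assert 0.0 <= p <= 1.0
        assert tk.cycle_transition_prob(m, 0.0, 0.7) == pytest.approx(
            1.0 - m.survival(0.7)
        )

    def test_zero_survival_guard(self):
        m = tk.SurvivalModel("exponential", (5.0,))
        with pytest.warns(RuntimeWarning):
            assert tk.cycle_transition_prob(m, 200.0, 0.25) == 1.0


class TestSelection:
    def _model(self, family, params, loglik, n=100):
        return tk.SurvivalModel(family, params, loglik=loglik, n_obs=n)

    def test_lowest_aic_wins(self):
        exp = self._model("exponential", (0.2,), loglik=-49.0)  # aic 100
        wb = self._model("weibull", (1.0, 5.0), loglik=-48.75)  # aic 101.5
        assert tk.select_model([exp, wb]).chosen == "exponential"

    def test_bic_breaks_aic_ties(self):
        # equal AIC by construction; exponential has the lower BIC
        exp = self._model("exponential", (0.2,), loglik=-50.0)  # aic 102
        wb = self._model("weibull", (1.0, 5.0), loglik=-49.0)  # aic 102
        sel = tk.select_model([exp, wb])
        assert exp.aic == wb.aic
        assert sel.chosen == "exponential"

    def test_empty_selection_raises(self):
        with pytest.raises(SelectionImpossibleError):
            tk.select_model([])

    def test_criterion_table_is_consistent(self):
        ipd = tk.simulate_ipd("exponential", (0.25,), n=300, censor_rate=0.05, seed=3)
        sel = tk.fit_all_families(ipd)
        tbl = sel.criterion_table()
        assert set(tbl["family"]) == set(tk.FAMILIES)
        assert tbl["chosen"].sum() == 1
        recomputed = 2 * tbl["n_params"] - 2 * tbl["loglik"]
        assert np.allclose(tbl["aic"], recomputed, atol=1e-9)

    def test_exponential_selected_on_exponential_data(self):
        """AIC selection should usually identify the generating family."""
        hits = 0
        for seed in range(10):
            ipd = tk.simulate_ipd("exponential", (0.2,), n=400, censor_rate=0.05,
                                  seed=100 + seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                sel = tk.fit_all_families(ipd)
            hits += sel.chosen == "exponential"
        assert hits >= 8

    def test_unknown_family_rejected(self):
        with pytest.raises(UnsupportedFamilyError):
            tk.fit_parametric((np.array([1.0]), np.array([1])), "gumbel")


class TestDensityConsistency:
    @pytest.mark.parametrize(
        "family,params",
        [
            ("weibull", (1.5, 3.0)),
            ("gamma", (2.0, 0.5)),
            ("generalized-gamma", (1.0, 0.7, -0.5)),
            ("gompertz", (0.2, 0.1)),
            ("log-logistic", (2.0, 3.0)),
        ],
    )
    def test_pdf_is_derivative_of_cdf(self, family, params):
        # f(t) ≈ −dS/dt by central differences
        p = np.asarray(params, dtype=float)
        t = np.linspace(0.5, 8.0, 30)
        h = 1e-5
        num = -(np.exp(_logsf(family, p, t + h)) - np.exp(_logsf(family, p, t - h))) / (2 * h)
        assert np.allclose(np.exp(_logpdf(family, p, t)), num, rtol=1e-4, atol=1e-8)
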