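"""Distribution layer: density, survival, defective mass, likelihood,
analytic gradients."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import norm

import fhtboost as fb
from fhtboost.distributions import fht_log_survival


def fd_loglik(t, d, mu, y0_eta, wrt, h=1e-6):
    """Central finite difference of the one-subject log-likelihood in mu
    or in eta = log(y0)."""
    data = fb.SurvivalData(np.array([t]), np.array([d]))

    def f(delta):
        m, e = mu, np.log(y0_eta)
        if wrt == "mu":
            m = mu + delta
        else:
            e = e + delta
        return fb.censored_loglik(data, np.array([m]), np.array([np.exp(e)]))

    return (f(h) - f(-h)) / (2 * h)


class TestDensityAndSurvival:
    def test_driftless_unit_level_density_is_standard_normal_at_one(self):
        assert fb.fht_pdf(1.0, mu=0.0, y0=1.0) == pytest.approx(norm.pdf(1.0), abs=1e-12)

    def test_density_vanishes_at_origin(self):
        assert fb.fht_pdf(1e-12, mu=-1.0, y0=2.0) == 0.0

    @pytest.mark.parametrize("mu,y0,mass", [
        (-1.0, 2.0, 1.0),
        (0.0, 1.5, 1.0),
        (1.0, 1.0, np.exp(-2.0)),
        (0.5, 2.0, np.exp(-2.0)),
    ])
    def test_total_mass_by_quadrature(self, mu, y0, mass):
        # proper law for mu <= 0; defective mass exp(-2 y0 mu) for mu > 0
        q, _ = quad(lambda t: fb.fht_pdf(t, mu=mu, y0=y0), 0, np.inf, limit=200)
        assert q == pytest.approx(mass, abs=1e-8)
        assert 1.0 - mass == pytest.approx(
            float(fb.prob_never_hit(mu=mu, y0=y0)), abs=1e-12)

    def test_cdf_matches_quadrature_of_density(self):
        q, _ = quad(lambda t: fb.fht_pdf(t, mu=-1.0, y0=2.0), 0, 3.0)
        assert fb.fht_cdf(3.0, mu=-1.0, y0=2.0) == pytest.approx(q, abs=1e-8)

    def test_cdf_limits(self):
        assert fb.fht_cdf(1e-10, mu=0.0, y0=1.0) == pytest.approx(0.0, abs=1e-12)
        assert fb.fht_cdf(1e9, mu=1.0, y0=1.0) == pytest.approx(np.exp(-2.0), abs=1e-9)
        assert fb.fht_survival(1e9, mu=1.0, y0=1.0) == pytest.approx(
            1 - np.exp(-2.0), abs=1e-9)

    def test_survival_near_zero_is_one(self):
        assert fb.fht_survival(1e-12, mu=-3.0, y0=0.5) == pytest.approx(1.0, abs=1e-12)

    @given(st.floats(-2.0, 2.0), st.floats(0.1, 5.0),
           st.floats(0.01, 50.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_survival_complements_cdf(self, mu, y0, t):
        s = fb.fht_survival(t, mu=mu, y0=y0)
        f = fb.fht_cdf(t, mu=mu, y0=y0)
        assert abs(s + f - 1.0) < 1e-12

    def test_survival_monotone_and_bounded(self):
        t = np.linspace(0.01, 60, 500)
        for mu, y0 in [(-1.0, 2.0), (0.0, 1.0), (0.7, 1.3)]:
            s = fb.fht_survival(t, mu=mu, y0=y0)
            assert np.all(np.diff(s) <= 1e-14)
            assert np.all((s >= 0) & (s <= 1))

    def test_pdf_is_derivative_of_cdf(self):
        t = np.linspace(0.2, 10, 60)
        h = 1e-6
        for mu, y0 in [(-1.0, 2.0), (0.5, 1.0)]:
            fd = (fb.fht_cdf(t + h, mu=mu, y0=y0) -
                  fb.fht_cdf(t - h, mu=mu, y0=y0)) / (2 * h)
            pdf = fb.fht_pdf(t, mu=mu, y0=y0)
            assert np.max(np.abs(fd - pdf) / np.maximum(pdf, 1e-10)) < 1e-6

    def test_domain_errors(self):
        with pytest.raises(fb.DomainError):
            fb.fht_pdf(-1.0, mu=0.0, y0=1.0)
        with pytest.raises(fb.DomainError):
            fb.fht_pdf(1.0, mu=0.0, y0=-1.0)
        with pytest.raises(fb.DomainError):
            fb.prob_never_hit(mu=1.0, y0=0.0)
        with pytest.raises(fb.DomainError):
            fb.IGFHTParams(mu=0.0, y0=-1.0)

    def test_params_object_interface(self):
        p = fb.IGFHTParams(mu=-1.0, y0=2.0)
        assert fb.fht_pdf(1.0, p) == fb.fht_pdf(1.0, mu=-1.0, y0=2.0)


class TestLoglik:
    def test_single_uncensored_matches_log_normal_density(self):
        data = fb.SurvivalData(np.array([1.0]), np.array([1]))
        ll = fb.censored_loglik(data, np.array([0.0]), np.array([1.0]))
        assert ll == pytest.approx(np.log(norm.pdf(1.0)), abs=1e-9)
        assert ll == pytest.approx(-1.418939, abs=1e-6)

    def test_single_censored_near_zero_time(self):
        data = fb.SurvivalData(np.array([1e-10]), np.array([0]))
        assert fb.censored_loglik(data, np.array([-1.0]), np.array([1.0])) == \
            pytest.approx(0.0, abs=1e-12)

    def test_additive_over_concatenation(self, random_param_batch):
        data, mu, y0 = random_param_batch(40)
        a = data.subset(slice(0, 25))
        b = data.subset(slice(25, 40))
        total = fb.censored_loglik(data, mu, y0)
        parts = (fb.censored_loglik(a, mu[:25], y0[:25]) +
                 fb.censored_loglik(b, mu[25:], y0[25:]))
        assert total == pytest.approx(parts, rel=1e-12)

    def test_all_events_equals_sum_of_logpdf(self, random_param_batch):
        data, mu, y0 = random_param_batch(30)
        all_ev = fb.SurvivalData(data.time, np.ones(30, dtype=int))
        from fhtboost.distributions import fht_logpdf

        assert fb.censored_loglik(all_ev, mu, y0) == pytest.approx(
            float(np.sum(fht_logpdf(data.time, mu=mu, y0=y0))), rel=1e-14)

    def test_survival_underflow_is_flagged_not_silent(self):
        # enormous negative drift at a late censoring time: S ~ 0
        data = fb.SurvivalData(np.array([1000.0]), np.array([0]))
        with pytest.raises(fb.NumericalFailure):
            fb.censored_loglik(data, np.array([-50.0]), np.array([1.0]))

    def test_non_finite_inputs_rejected(self):
        data = fb.SurvivalData(np.array([1.0]), np.array([1]))
        with pytest.raises(fb.DomainError):
            fb.censored_loglik(data, np.array([np.nan]), np.array([1.0]))
        with pytest.raises(fb.DomainError):
            fb.censored_loglik(data, np.array([0.0]), np.array([-2.0]))


class TestGradients:
    @pytest.mark.parametrize("t,mu,y0,expected", [
        (1.0, 0.0, 1.0, -1.0),
        (2.0, -1.0, 2.0, 0.0),
    ])
    def test_uncensored_drift_gradient_closed_form(self, t, mu, y0, expected):
        data = fb.SurvivalData(np.array([t]), np.array([1]))
        g = fb.grad_mu(data, np.array([mu]), np.array([y0]))
        assert g[0] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("t,mu,y0,expected", [
        (1.0, 0.0, 1.0, 0.0),
        (1.0, -1.0, 2.0, -1.0),
    ])
    def test_uncensored_level_gradient_closed_form(self, t, mu, y0, expected):
        # chain rule through the log link: y0 * (1/y0 - (y0 + mu t)/t)
        data = fb.SurvivalData(np.array([t]), np.array([1]))
        g = fb.grad_eta_y0(data, np.array([mu]), np.array([y0]))
        assert g[0] == pytest.approx(expected, abs=1e-12)

    def test_censored_gradients_match_finite_differences(self):
        data = fb.SurvivalData(np.array([1.0]), np.array([0]))
        g_mu = fb.grad_mu(data, np.array([-0.5]), np.array([1.0]))[0]
        g_eta = fb.grad_eta_y0(data, np.array([-0.5]), np.array([1.0]))[0]
        assert g_mu == pytest.approx(fd_loglik(1.0, 0, -0.5, 1.0, "mu"), rel=1e-6)
        assert g_eta == pytest.approx(fd_loglik(1.0, 0, -0.5, 1.0, "eta"), rel=1e-6)

    def test_gradients_match_finite_differences_on_random_batches(
            self, random_param_batch):
        """Both analytic gradients vs central differences, 1000 randomized
        censored/uncensored cases, relative error < 1e-6."""
        data, mu, y0 = random_param_batch(1000)
        g_mu = fb.grad_mu(data, mu, y0)
        g_eta = fb.grad_eta_y0(data, mu, y0)
        for i in range(data.n):
            for g, wrt in ((g_mu, "mu"), (g_eta, "eta")):
                fd = fd_loglik(data.time[i], data.event[i], mu[i], y0[i], wrt)
                denom = max(abs(fd), 1e-4)
                assert abs(g[i] - fd) / denom < 1e-6, (i, wrt, g[i], fd)

    def test_gradient_sign_behaviour_for_censored_subject(self):
        # raising the level of a censored subject raises log S
        data = fb.SurvivalData(np.array([2.0]), np.array([0]))
        assert fb.grad_eta_y0(data, np.array([-1.0]), np.array([1.5]))[0] > 0


def test_log_survival_agrees_with_direct_formula_in_safe_region():
    t = np.linspace(0.5, 20, 50)
    for mu, y0 in [(-1.0, 2.0), (0.3, 1.0)]:
        direct = np.log(norm.cdf((mu * t + y0) / np.sqrt(t)) -
                        np.exp(-2 * y0 * mu) * norm.cdf((mu * t - y0) / np.sqrt(t)))
        assert np.allclose(fht_log_survival(t, mu=mu, y0=y0), direct,
                           rtol=1e-10, atol=1e-12)
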