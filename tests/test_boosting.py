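"""Boosting engine: null model, component-wise selection, both variants."""

import numpy as np
import pytest

import fhtboost as fb
from fhtboost.boosting import _ls_updates


def brute_force_selection(u, X, nu, loss_fn):
    """Exhaustive enumeration oracle: direct least-squares formulas per
    column, tentative loss of each, argmin with smallest-index ties."""
    best = None
    for j in range(X.shape[1]):
        x = X[:, j]
        xbar, ubar = x.mean(), u.mean()
        sxx = np.sum((x - xbar) ** 2)
        b = 0.0 if sxx == 0 else np.sum((u - ubar) * (x - xbar)) / sxx
        a = ubar - b * xbar
        loss = loss_fn(nu * a, nu * b, j)
        if best is None or loss < best[3] - 1e-15:
            best = (j, nu * a, nu * b, loss)
    return best


class TestNullModel:
    def test_recovers_constant_truth_on_large_sample(self):
        design = fb.SimulationDesign(n=20000, beta=np.array([-1.0]),
                                     gamma=np.array([2.0]),
                                     censoring_rate=0.0, seed=3)
        data, _, _ = fb.simulate_dataset(design)
        beta0, gamma0 = fb.initialize_null_model(data)
        assert beta0 == pytest.approx(-1.0, abs=0.02)
        assert gamma0 == pytest.approx(2.0, abs=0.02)

    def test_stationarity_at_optimum(self, reference_dataset):
        data, _, _ = reference_dataset
        beta0, gamma0 = fb.initialize_null_model(data)
        h = 1e-5
        mu = np.full(data.n, beta0)
        y0 = np.full(data.n, np.exp(gamma0))
        base_mu = fb.grad_mu(data, mu, y0).sum()
        base_eta = fb.grad_eta_y0(data, mu, y0).sum()
        assert abs(base_mu) < 1e-4 * data.n
        assert abs(base_eta) < 1e-4 * data.n
        # finite-difference corroboration of both directions
        ll = fb.censored_loglik(data, mu, y0)
        ll_mu = fb.censored_loglik(data, mu + h, y0)
        ll_eta = fb.censored_loglik(data, mu, y0 * np.exp(h))
        assert abs(ll_mu - ll) / h < 1e-2
        assert abs(ll_eta - ll) / h < 1e-2

    def test_invariant_to_subject_permutation(self, reference_dataset):
        data, _, _ = reference_dataset
        perm = np.random.default_rng(0).permutation(data.n)
        a = fb.initialize_null_model(data)
        b = fb.initialize_null_model(data.subset(perm))
        assert a == pytest.approx(b, rel=1e-8)

    def test_zero_events_rejected(self):
        data = fb.SurvivalData(np.ones(5), np.zeros(5, dtype=int))
        with pytest.raises(fb.FittingError):
            fb.initialize_null_model(data)


class TestComponentwiseStep:
    def test_single_column_always_selected(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=8)
        X = rng.normal(size=(8, 1))
        j, a, b, _ = fb.componentwise_step(u, X, 0.1,
                                           lambda aa, bb: np.zeros(aa.size))
        assert j == 0

    def test_orthogonal_mean_zero_gradient_gives_null_update(self):
        X = np.array([[1.0, 2.0], [-1.0, 2.0], [1.0, -2.0], [-1.0, -2.0]])
        u = np.array([1.0, -1.0, -1.0, 1.0])  # mean 0, orthogonal to centered X
        assert abs(u.mean()) < 1e-15
        assert np.allclose((X - X.mean(0)).T @ u, 0)
        losses = []

        def loss_of(a, b):
            losses.append((a.copy(), b.copy()))
            return np.zeros(a.size)

        _, a, b, _ = fb.componentwise_step(u, X, 0.1, loss_of)
        assert a == 0.0 and b == 0.0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(5)
        n, p = 5, 3
        X = rng.normal(size=(n, p))
        u = rng.normal(size=n)
        # arbitrary smooth surrogate loss of the tentative updates
        t = rng.uniform(1, 2, n)

        def tentative_loss(a, b, j):
            fit = a + b * X[:, j]
            return float(np.sum((u - fit) ** 2 * t))

        def loss_of(a, b):
            return np.array([tentative_loss(a[j], b[j], j)
                             for j in range(p)])

        got = fb.componentwise_step(u, X, 0.1, loss_of)
        want = brute_force_selection(u, X, 0.1, tentative_loss)
        assert got[0] == want[0]
        assert got[1] == pytest.approx(want[1], rel=1e-12)
        assert got[2] == pytest.approx(want[2], rel=1e-12)

    def test_zero_variance_column_gets_intercept_only_fit(self):
        X = np.column_stack([np.ones(6), np.arange(6.0)])
        u = np.arange(6.0) - 2.5
        a, b = _ls_updates(u, X)
        assert b[0] == 0.0
        assert a[0] == pytest.approx(u.mean())
        assert b[1] == pytest.approx(1.0)

    def test_gradient_rss_rule_picks_best_correlated_column(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 4))
        u = 2.0 * X[:, 2] + 0.01 * rng.normal(size=50)
        calls = []

        def loss_of(a, b):
            calls.append(a.size)
            return np.zeros(a.size)

        j, *_ = fb.componentwise_step(u, X, 0.1, loss_of,
                                      selection_rule="gradient_rss")
        assert j == 2
        assert calls == [1]  # loss evaluated only for the winner


class TestCyclical:
    def test_zero_iterations_returns_null_model(self, reference_dataset):
        data, designs, _ = reference_dataset
        state, trace = fb.boost_cyclical(
            data, designs, fb.BoostingConfig(mstop_mu=0, mstop_y0=0))
        beta0, gamma0 = fb.initialize_null_model(data)
        assert state.beta == pytest.approx([beta0, 0.0, 0.0])
        assert state.gamma == pytest.approx([gamma0, 0.0, 0.0])
        assert trace.iterations == [0]

    def test_converges_to_joint_mle(self, reference_dataset, mle_oracle):
        """With unlimited iterations in a low-dimensional problem the
        coefficient path reaches the joint maximum-likelihood fit."""
        data, designs, _ = reference_dataset
        state, trace = fb.boost_cyclical(
            data, designs, fb.BoostingConfig(mstop_mu=10000, mstop_y0=10000))
        mle = mle_oracle(data, designs)
        got = np.concatenate([state.beta, state.gamma])
        assert np.max(np.abs(got - mle)) < 0.01

    def test_single_covariate_moves_per_parameter_per_iteration(
            self, reference_dataset):
        data, designs, _ = reference_dataset
        _, trace = fb.boost_cyclical(
            data, designs, fb.BoostingConfig(mstop_mu=30, mstop_y0=30))
        for k in range(1, len(trace.snapshots)):
            prev, cur = trace.snapshots[k - 1], trace.snapshots[k]
            assert np.sum(cur.beta[1:] != prev.beta[1:]) <= 1
            assert np.sum(cur.gamma[1:] != prev.gamma[1:]) <= 1
        # intercepts move together with the selected covariates
        b0 = np.array([s.beta[0] for s in trace.snapshots])
        assert np.any(np.diff(b0) != 0)

    def test_training_loss_non_increasing(self, reference_dataset):
        data, designs, _ = reference_dataset
        _, trace = fb.boost_cyclical(
            data, designs, fb.BoostingConfig(mstop_mu=100, mstop_y0=100))
        assert np.all(np.diff(trace.losses) <= 1e-10)

    def test_early_stopping_shrinks_toward_zero_relative_to_mle(
            self, reference_dataset, mle_oracle):
        data, designs, _ = reference_dataset
        mle = mle_oracle(data, designs)
        _, trace = fb.boost_cyclical(
            data, designs, fb.BoostingConfig(mstop_mu=200, mstop_y0=200))
        mle_slopes = np.abs(np.concatenate([mle[1:3], mle[4:6]]))
        for s in trace.snapshots:
            slopes = np.abs(np.concatenate([s.beta[1:], s.gamma[1:]]))
            assert np.all(slopes <= mle_slopes + 0.01)

    def test_asymmetric_stopping_freezes_one_side(self, reference_dataset):
        data, designs, _ = reference_dataset
        state, trace = fb.boost_cyclical(
            data, designs, fb.BoostingConfig(mstop_mu=5, mstop_y0=12))
        assert len(trace.iterations) == 13
        beta_after_5 = trace.snapshots[5].beta
        assert np.array_equal(trace.snapshots[12].beta, beta_after_5)

    def test_bit_identical_reproducibility(self, reference_dataset):
        data, designs, _ = reference_dataset
        cfg = fb.BoostingConfig(mstop_mu=40, mstop_y0=40)
        s1, t1 = fb.boost_cyclical(data, designs, cfg)
        s2, t2 = fb.boost_cyclical(data, designs, cfg)
        assert np.array_equal(s1.beta, s2.beta)
        assert np.array_equal(s1.gamma, s2.gamma)
        assert t1.losses == t2.losses
        assert t1.updated == t2.updated


class TestNoncyclical:
    def test_zero_iterations_returns_null_model(self, reference_dataset):
        data, designs, _ = reference_dataset
        state, _ = fb.boost_noncyclical(
            data, designs, fb.BoostingConfig(variant="noncyclical", mstop=0))
        assert np.all(state.beta[1:] == 0) and np.all(state.gamma[1:] == 0)

    def test_updates_exactly_one_parameter_per_iteration(self, reference_dataset):
        data, designs, _ = reference_dataset
        _, trace = fb.boost_noncyclical(
            data, designs, fb.BoostingConfig(variant="noncyclical", mstop=60))
        for upd in trace.updated[1:]:
            assert len(upd) == 1
            assert upd[0].split(":")[0] in ("mu", "y0")

    def test_signal_concentrated_on_drift_gets_mostly_drift_updates(self):
        """When only the drift-side covariates carry signal, the
        parameter-selection step should overwhelmingly pick the drift."""
        design = fb.SimulationDesign(
            n=300, beta=np.array([-1.0, -1.0, 1.0]),
            gamma=np.array([2.0, 0.0, 0.0]), censoring_rate=0.05, seed=9)
        data, designs, _ = fb.simulate_dataset(design)
        res = fb.cv_select(data, designs,
                           fb.BoostingConfig(variant="noncyclical"),
                           fb.CVPlan(K=4, max_mstop=120, seed=9))
        _, trace = fb.boost_noncyclical(
            data, designs,
            fb.BoostingConfig(variant="noncyclical", mstop=res.chosen[0]))
        sides = [u[0].split(":")[0] for u in trace.updated[1:] if u]
        assert sides.count("mu") / len(sides) > 0.6

    def test_loss_non_increasing(self, reference_dataset):
        data, designs, _ = reference_dataset
        _, trace = fb.boost_noncyclical(
            data, designs, fb.BoostingConfig(variant="noncyclical", mstop=150))
        assert np.all(np.diff(trace.losses) <= 1e-10)


class TestVariantAgreement:
    def test_both_variants_reach_the_same_optimum(self, reference_dataset,
                                                  mle_oracle):
        """Cyclical (m, m) and non-cyclical (2m) both converge to the
        unique joint MLE in the low-dimensional limit."""
        data, designs, _ = reference_dataset
        m = 3000
        cy, _ = fb.boost_cyclical(
            data, designs, fb.BoostingConfig(mstop_mu=m, mstop_y0=m))
        nc, _ = fb.boost_noncyclical(
            data, designs, fb.BoostingConfig(variant="noncyclical", mstop=2 * m))
        a = np.concatenate([cy.beta, cy.gamma])
        b = np.concatenate([nc.beta, nc.gamma])
        assert np.max(np.abs(a - b)) < 0.02
        mle = mle_oracle(data, designs)
        assert np.max(np.abs(a - mle)) < 0.02


class TestFailureHandling:
    def test_retry_helper_shrinks_step_size(self, monkeypatch):
        calls = []

        def fake_boost(data, designs, config):
            calls.append(config.nu)
            if len(calls) == 1:
                raise fb.NumericalFailure("boom", iteration=3)
            return "state", "trace"

        monkeypatch.setattr("fhtboost.boosting.boost", fake_boost)
        from fhtboost.boosting import boost_with_retry

        out = boost_with_retry(None, None, fb.BoostingConfig(mstop_mu=10),
                               max_retries=1)
        assert out == ("state", "trace")
        assert calls == [0.1, pytest.approx(0.01)]

    def test_standardize_flag_returns_original_scale_coefficients(
            self, reference_dataset):
        data, designs, _ = reference_dataset
        plain, _ = fb.boost_cyclical(
            data, designs, fb.BoostingConfig(mstop_mu=5000, mstop_y0=5000))
        std, _ = fb.boost_cyclical(
            data, designs,
            fb.BoostingConfig(mstop_mu=5000, mstop_y0=5000, standardize=True))
        # near convergence both parameterizations give the same optimum
        assert np.allclose(plain.beta, std.beta, atol=5e-3)
        assert np.allclose(plain.gamma, std.gamma, atol=5e-3)
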