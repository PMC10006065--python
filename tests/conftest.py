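import numpy as np
import pytest

import fhtboost as fb


@pytest.fixture(scope="session")
def reference_dataset():
    """One realization of the low-dimensional reference scenario:
    n=200, drift -1 - 0.1 c1 + 0.1 c2, level log y0 = 2 + 0.1 g1 + 0.2 g2,
    Exp(0.1) censoring."""
    return fb.simulate_dataset(fb.reference_design(seed=1))


@pytest.fixture(scope="session")
def mle_oracle():
    """Joint maximum-likelihood fit by a direct numerical optimizer,
    independent of the boosting path."""
    from scipy.optimize import minimize

    def solve(data, designs, x0=None):
        p_mu, p_y0 = designs.p_mu, designs.p_y0

        def negll(theta):
            beta, gamma = theta[:p_mu + 1], theta[p_mu + 1:]
            mu = beta[0] + designs.X_mu @ beta[1:]
            eta = gamma[0] + designs.X_y0 @ gamma[1:]
            try:
                return -fb.censored_loglik(data, mu, np.exp(eta))
            except fb.FHTBoostError:
                return np.inf

        def grad(theta):
            beta, gamma = theta[:p_mu + 1], theta[p_mu + 1:]
            mu = beta[0] + designs.X_mu @ beta[1:]
            eta = gamma[0] + designs.X_y0 @ gamma[1:]
            gm = fb.grad_mu(data, mu, np.exp(eta))
            ge = fb.grad_eta_y0(data, mu, np.exp(eta))
            return -np.concatenate([[gm.sum()], designs.X_mu.T @ gm,
                                    [ge.sum()], designs.X_y0.T @ ge])

        if x0 is None:
            x0 = np.zeros(p_mu + p_y0 + 2)
            x0[0], x0[p_mu + 1] = -1.0, np.log(max(np.mean(data.time), 1e-3))
        res = minimize(negll, x0, jac=grad, method="BFGS",
                       options={"gtol": 1e-9, "maxiter": 2000})
        assert np.max(np.abs(res.jac)) < 1e-5, "oracle optimizer not stationary"
        return res.x

    return solve


@pytest.fixture()
def random_param_batch():
    """Randomized (t, d, mu, y0) batches in the numerically comfortable
    regime, for gradient checks."""
    rng = np.random.default_rng(42)

    def make(n):
        t = rng.uniform(0.05, 15.0, n)
        d = rng.integers(0, 2, n)
        mu = rng.normal(-0.6, 0.6, n)
        y0 = np.exp(rng.normal(0.5, 0.6, n))
        return fb.SurvivalData(t, d), mu, y0

    return make
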