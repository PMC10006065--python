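"""Component-wise gradient boosting of the two-parameter hitting-time model.

Both distribution parameters get their own linear predictor: the drift
mu (identity link, coefficients beta) and the log initial level
(coefficients gamma). Starting from the intercept-only maximum-likelihood
fit, each boosting iteration fits a simple linear base learner
(intercept + one covariate) to the negative gradient of the empirical
loss — the negative censored log-likelihood — separately for every
candidate covariate, tentatively applies each nu-scaled update, and keeps
the single covariate whose update lowers the training loss the most. Only
one covariate per parameter moves per iteration, which gives the
algorithm its intrinsic variable selection, and early stopping acts as
shrinkage.

Two variants are provided. The *cyclical* variant updates the drift and
then the level in every iteration, each with its own stopping iteration
(``mstop_mu``, ``mstop_y0``). The *non-cyclical* variant computes the
best candidate update for each parameter and applies only the one with
the lower resulting loss, so a single ``mstop`` governs the whole path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .data import CoefficientState, DesignPair, SurvivalData
from .distributions import censored_loglik, fht_logpdf, fht_log_survival, grad_eta_y0, grad_mu
from .exceptions import ConfigError, FittingError, NumericalFailure

__all__ = [
    "BoostingConfig",
    "BoostingTrace",
    "initialize_null_model",
    "componentwise_step",
    "boost_cyclical",
    "boost_noncyclical",
    "boost",
    "boost_with_retry",
]


@dataclass(frozen=True)
class BoostingConfig:
    """Hyperparameters of a boosting run.

    nu : step size in (0, 1]; 0.1 by default, kept deliberately small so
        each update is weak.
    mstop_mu, mstop_y0 : stopping iterations of the two parameters
        (cyclical variant).
    mstop : total number of iterations (non-cyclical variant).
    variant : "cyclical" or "noncyclical".
    selection_rule : "loss_reduction" evaluates the training loss of each
        tentative update (the reference criterion); "gradient_rss" picks
        the base learner with the smallest residual sum of squares, which
        is cheaper by a factor of p.
    standardize : opt-in scaling of covariates to unit variance during
        fitting; coefficients are reported on the original scale.
    """

    nu: float = 0.1
    mstop_mu: int = 0
    mstop_y0: int = 0
    mstop: int = 0
    variant: str = "cyclical"
    selection_rule: str = "loss_reduction"
    standardize: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.nu <= 1.0:
            raise ConfigError("nu must lie in (0, 1]")
        if self.variant not in ("cyclical", "noncyclical"):
            raise ConfigError(f"unknown variant {self.variant!r}")
        if self.selection_rule not in ("loss_reduction", "gradient_rss"):
            raise ConfigError(f"unknown selection_rule {self.selection_rule!r}")
        for name in ("mstop_mu", "mstop_y0", "mstop"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")


@dataclass
class BoostingTrace:
    """Per-iteration record of a boosting run.

    Iteration 0 is the null model. ``updated`` holds the component names
    touched in each iteration, e.g. ``("mu:age", "y0:geneX")`` for a
    cyclical step or a single entry for a non-cyclical one.
    """

    mu_names: list
    y0_names: list
    iterations: list = field(default_factory=list)
    updated: list = field(default_factory=list)
    snapshots: list = field(default_factory=list)
    losses: list = field(default_factory=list)

    def record(self, iteration: int, updated: tuple, state: CoefficientState,
               loss: float):
        self.iterations.append(iteration)
        self.updated.append(tuple(updated))
        self.snapshots.append(state.copy())
        self.losses.append(float(loss))

    def to_frame(self) -> pd.DataFrame:
        """Long coefficient path: one row per iteration, one column per
        coefficient, plus the updated components and the training loss."""
        cols = {}
        cols["iteration"] = self.iterations
        cols["updated"] = ["+".join(u) if u else "" for u in self.updated]
        beta = np.array([s.beta for s in self.snapshots])
        gamma = np.array([s.gamma for s in self.snapshots])
        cols["beta_0"] = beta[:, 0]
        for j, name in enumerate(self.mu_names):
            cols[f"beta_{name}"] = beta[:, j + 1]
        cols["gamma_0"] = gamma[:, 0]
        for j, name in enumerate(self.y0_names):
            cols[f"gamma_{name}"] = gamma[:, j + 1]
        cols["train_loss"] = self.losses
        return pd.DataFrame(cols)


def initialize_null_model(data: SurvivalData) -> tuple[float, float]:
    """Intercepts of the null model: the constant-parameter MLE.

    Maximizes the censored log-likelihood over (mu, log y0) with analytic
    gradients. Deterministic given the data; requires at least one event.
    """
    if data.n_events == 0:
        raise FittingError("cannot initialize the null model on data with zero events")

    def neg_ll_and_grad(theta):
        mu = np.full(data.n, theta[0])
        y0 = np.full(data.n, np.exp(theta[1]))
        try:
            ll = censored_loglik(data, mu, y0)
            g = np.array([grad_mu(data, mu, y0).sum(),
                          grad_eta_y0(data, mu, y0).sum()])
        except NumericalFailure:
            return np.inf, np.zeros(2)
        return -ll, -g

    # Moment-flavoured start: mean hitting time of the proper law is
    # y0/|mu|, so mu = -1, y0 = mean(t) is a reasonable basin.
    starts = [np.array([-1.0, np.log(max(np.mean(data.time), 1e-3))]),
              np.array([-0.5, 0.0]),
              np.array([-2.0, 1.0])]
    best = None
    for x0 in starts:
        res = minimize(neg_ll_and_grad, x0, jac=True, method="L-BFGS-B",
                       options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10})
        if best is None or (res.success and res.fun < best.fun) or \
           (not best.success and res.fun < best.fun):
            best = res
        if res.success and np.max(np.abs(res.jac)) < 1e-6:
            best = res
            break
    if best is None or not np.all(np.isfinite(best.x)):
        raise FittingError("null-model optimization failed", detail=best)
    if np.max(np.abs(best.jac)) > 1e-4:
        raise FittingError(
            "null-model optimizer did not reach a stationary point", detail=best)
    return float(best.x[0]), float(best.x[1])


def _ls_updates(u: np.ndarray, X: np.ndarray):
    """Simple least-squares fits of u on (1, x_j) for every column j.

    Returns (intercepts a_j, slopes b_j), unscaled. Zero-variance columns
    get slope 0 and the intercept-only fit mean(u).
    """
    n = u.size
    ubar = u.mean()
    xbar = X.mean(axis=0)
    xc = X - xbar
    sxx = np.einsum("ij,ij->j", xc, xc)
    sxu = (u - ubar) @ xc
    with np.errstate(invalid="ignore", divide="ignore"):
        b = np.where(sxx > 0, sxu / np.where(sxx > 0, sxx, 1.0), 0.0)
    a = ubar - b * xbar
    return a, b


class _LossEvaluator:
    """Training-loss evaluations, vectorized over candidate updates.

    Holds the survival data and the *other* parameter's linear predictor
    fixed, and evaluates the negative censored log-likelihood for an
    n-by-k matrix of tentative predictors in one pass.
    """

    def __init__(self, data: SurvivalData):
        self.t = data.time
        self.ev = data.event == 1
        self.cn = ~self.ev

    def loss_matrix(self, mu_mat: np.ndarray, y0_mat: np.ndarray) -> np.ndarray:
        """Column k -> negative log-likelihood of (mu_mat[:,k], y0_mat[:,k])."""
        t = self.t[:, None]
        out = np.zeros(mu_mat.shape[1])
        if self.ev.any():
            lp = fht_logpdf(t[self.ev], mu=mu_mat[self.ev], y0=y0_mat[self.ev])
            out -= lp.sum(axis=0)
        if self.cn.any():
            ls = fht_log_survival(t[self.cn], mu=mu_mat[self.cn],
                                  y0=y0_mat[self.cn], raise_on_underflow=False)
            out -= ls.sum(axis=0)
        return out


def componentwise_step(u: np.ndarray, X: np.ndarray, nu: float,
                       loss_of_updates, selection_rule: str = "loss_reduction"):
    """One component-wise base-learner selection.

    Fits u on (intercept, x_j) for every column j, scales the fits by nu
    and asks ``loss_of_updates(a, b)`` — a callable mapping the arrays of
    nu-scaled intercept and slope updates to the per-column training loss
    of the tentatively updated model — which column wins. Ties go to the
    smallest index. Under ``gradient_rss`` the column with the smallest
    base-learner residual sum of squares wins instead, and the loss is
    evaluated only for that column.

    Returns ``(j_star, intercept_update, slope_update, achieved_loss)``.
    """
    if X.shape[1] == 0:
        raise ConfigError("componentwise_step requires at least one column")
    a, b = _ls_updates(u, X)
    a = nu * a
    b = nu * b
    if selection_rule == "gradient_rss":
        n = u.size
        ubar = u.mean()
        # RSS of each simple fit; selectable only if the slope is nonzero.
        xc = X - X.mean(axis=0)
        sxx = np.einsum("ij,ij->j", xc, xc)
        sst = np.sum((u - ubar) ** 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            rss = sst - np.where(sxx > 0, ((u - ubar) @ xc) ** 2 / np.where(sxx > 0, sxx, 1.0), 0.0)
        j = int(np.argmin(rss))
        loss = float(np.asarray(loss_of_updates(a[j:j + 1], b[j:j + 1]))[0])
        return j, float(a[j]), float(b[j]), loss
    losses = np.asarray(loss_of_updates(a, b), dtype=float)
    # Zero-variance columns reduce to intercept-only fits; they are never
    # preferred over an identical-loss genuine column because ties break
    # to the smallest index among the true minima.
    j = int(np.argmin(losses))
    return j, float(a[j]), float(b[j]), float(losses[j])


class _Standardizer:
    """Unit-variance scaling of a design matrix, with coefficient back-map."""

    def __init__(self, X: np.ndarray, enabled: bool):
        self.enabled = enabled and X.shape[1] > 0
        if self.enabled:
            sd = X.std(axis=0, ddof=0)
            self.scale = np.where(sd > 0, sd, 1.0)
            self.X = X / self.scale
        else:
            self.scale = None
            self.X = X

    def to_original(self, coefs: np.ndarray) -> np.ndarray:
        if not self.enabled:
            return coefs
        out = coefs.copy()
        out[1:] = coefs[1:] / self.scale
        return out


class _Fitter:
    """Shared state of one boosting run (either variant)."""

    def __init__(self, data: SurvivalData, designs: DesignPair,
                 config: BoostingConfig):
        self.data = data
        self.config = config
        self.designs = designs
        self.std_mu = _Standardizer(designs.X_mu, config.standardize)
        self.std_y0 = _Standardizer(designs.X_y0, config.standardize)
        self.X_mu = self.std_mu.X
        self.X_y0 = self.std_y0.X
        self.evaluator = _LossEvaluator(data)
        beta0, gamma0 = initialize_null_model(data)
        self.state = CoefficientState.null(beta0, gamma0, designs.p_mu, designs.p_y0)
        self.mu = np.full(data.n, beta0)
        self.eta = np.full(data.n, gamma0)
        self.trace = BoostingTrace(designs.mu_names, designs.y0_names)
        self.trace.record(0, (), self._external_state(), self.current_loss())

    def _external_state(self) -> CoefficientState:
        return CoefficientState(self.std_mu.to_original(self.state.beta),
                                self.std_y0.to_original(self.state.gamma))

    def current_loss(self) -> float:
        return float(self.evaluator.loss_matrix(self.mu[:, None],
                                                np.exp(self.eta[:, None]))[0])

    def _guard(self, value, iteration: int, quantity: str):
        if not np.all(np.isfinite(value)):
            raise NumericalFailure(
                f"non-finite {quantity} at boosting iteration {iteration}; "
                "consider a smaller step size nu",
                iteration=iteration, quantity=quantity)
        return value

    # -- candidate computation ------------------------------------------

    def candidate_mu(self, iteration: int):
        u = self._guard(grad_mu(self.data, self.mu, np.exp(self.eta)),
                        iteration, "drift gradient")

        def loss_of(a, b):
            mu_mat = self.mu[:, None] + a[None, :] + self.X_mu * b[None, :]
            return self.evaluator.loss_matrix(
                mu_mat, np.broadcast_to(np.exp(self.eta)[:, None], mu_mat.shape))

        return componentwise_step(u, self.X_mu, self.config.nu, loss_of,
                                  self.config.selection_rule)

    def candidate_y0(self, iteration: int):
        u = self._guard(grad_eta_y0(self.data, self.mu, np.exp(self.eta)),
                        iteration, "level gradient")

        def loss_of(a, b):
            eta_mat = self.eta[:, None] + a[None, :] + self.X_y0 * b[None, :]
            return self.evaluator.loss_matrix(
                np.broadcast_to(self.mu[:, None], eta_mat.shape), np.exp(eta_mat))

        return componentwise_step(u, self.X_y0, self.config.nu, loss_of,
                                  self.config.selection_rule)

    # -- update application ---------------------------------------------

    def apply_mu(self, j: int, a: float, b: float) -> str:
        self.state.beta[0] += a
        self.state.beta[j + 1] += b
        self.mu = self.mu + a + b * self.X_mu[:, j]
        return f"mu:{self.designs.mu_names[j]}"

    def apply_y0(self, j: int, a: float, b: float) -> str:
        self.state.gamma[0] += a
        self.state.gamma[j + 1] += b
        self.eta = self.eta + a + b * self.X_y0[:, j]
        return f"y0:{self.designs.y0_names[j]}"


def boost_cyclical(data: SurvivalData, designs: DesignPair,
                   config: BoostingConfig):
    """Cyclical variant: update the drift, then the level, every iteration.

    The drift side stops after ``mstop_mu`` iterations and the level side
    after ``mstop_y0``; the run lasts max(mstop_mu, mstop_y0) iterations.
    The level-side gradient is recomputed after the drift update of the
    same iteration (sequential, not parallel, updates).

    Returns ``(final CoefficientState, BoostingTrace)``.
    """
    if config.variant != "cyclical":
        raise ConfigError("boost_cyclical requires variant='cyclical'")
    fitter = _Fitter(data, designs, config)
    total = max(config.mstop_mu, config.mstop_y0)
    for m in range(1, total + 1):
        updated = []
        loss = fitter.trace.losses[-1]
        if m <= config.mstop_mu and designs.p_mu > 0:
            j, a, b, loss = fitter.candidate_mu(m)
            fitter._guard(loss, m, "training loss")
            updated.append(fitter.apply_mu(j, a, b))
        if m <= config.mstop_y0 and designs.p_y0 > 0:
            j, a, b, loss = fitter.candidate_y0(m)
            fitter._guard(loss, m, "training loss")
            updated.append(fitter.apply_y0(j, a, b))
        fitter.trace.record(m, tuple(updated), fitter._external_state(), loss)
    return fitter._external_state(), fitter.trace


def boost_noncyclical(data: SurvivalData, designs: DesignPair,
                      config: BoostingConfig):
    """Non-cyclical variant: one parameter updated per iteration.

    Both candidate updates are computed at the current state; the one
    achieving the lower training loss is applied (ties favour the drift).
    A single ``mstop`` controls the whole path, which makes tuning a
    one-dimensional search.
    """
    if config.variant != "noncyclical":
        raise ConfigError("boost_noncyclical requires variant='noncyclical'")
    fitter = _Fitter(data, designs, config)
    for m in range(1, config.mstop + 1):
        cand = []
        if designs.p_mu > 0:
            cand.append(("mu", fitter.candidate_mu(m)))
        if designs.p_y0 > 0:
            cand.append(("y0", fitter.candidate_y0(m)))
        if not cand:
            fitter.trace.record(m, (), fitter._external_state(),
                                fitter.trace.losses[-1])
            continue
        # min() is stable: on ties the first (mu) candidate wins.
        side, (j, a, b, loss) = min(cand, key=lambda c: c[1][3])
        fitter._guard(loss, m, "training loss")
        name = fitter.apply_mu(j, a, b) if side == "mu" else fitter.apply_y0(j, a, b)
        fitter.trace.record(m, (name,), fitter._external_state(), loss)
    return fitter._external_state(), fitter.trace


def boost(data: SurvivalData, designs: DesignPair, config: BoostingConfig):
    """Dispatch on ``config.variant``."""
    if config.variant == "cyclical":
        return boost_cyclical(data, designs, config)
    return boost_noncyclical(data, designs, config)


def boost_with_retry(data: SurvivalData, designs: DesignPair,
                     config: BoostingConfig, *, max_retries: int = 1):
    """Run :func:`boost`; on numerical failure retry with nu/10, 10x mstop.

    Mirrors the standard remediation for non-smooth likelihood regions:
    a slower path can avoid them. Raises the last failure if all retries
    are exhausted.
    """
    attempt = config
    for _ in range(max_retries + 1):
        try:
            return boost(data, designs, attempt)
        except NumericalFailure as err:
            last = err
            attempt = replace(attempt, nu=attempt.nu / 10.0,
                              mstop_mu=attempt.mstop_mu * 10,
                              mstop_y0=attempt.mstop_y0 * 10,
                              mstop=attempt.mstop * 10)
    raise last
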