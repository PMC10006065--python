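r"""Inverse-Gaussian first-hitting-time distribution and its likelihood.

The event time is modelled as the first time a latent Wiener "health"
process :math:`Y(t) = y_0 + \mu t + \sigma W(t)` (initial level
:math:`y_0 > 0`, drift :math:`\mu`, diffusion :math:`\sigma`) reaches
zero. The hitting time then follows an inverse-Gaussian law with density

.. math::

    f(t) = \frac{y_0}{\sqrt{2\pi\sigma^2 t^3}}
           \exp\!\left[-\frac{(\mu t + y_0)^2}{2\sigma^2 t}\right],

which is *defective* when the drift points away from the boundary
(:math:`\mu > 0`): the process escapes with probability
:math:`1 - \exp(-2 y_0 \mu / \sigma^2)` and the event never occurs.
Because density and survival depend on the parameters only through
:math:`\mu/\sigma` and :math:`y_0/\sigma`, :math:`\sigma` is fixed to 1
throughout and the ``sigma`` field exists only for documentation.

The censored log-likelihood sums :math:`d_i \log f(t_i) +
(1 - d_i)\log S(t_i)` over subjects. Its per-subject partial derivatives
with respect to :math:`\mu_i` and to the log-level linear predictor
:math:`\eta_i = \log y_{0i}` are the negative-gradient vectors the
boosting engine fits base learners to. They are implemented analytically
from the log-likelihood itself and are verified against finite
differences in the test suite.

The survival function

.. math::

    S(t) = \Phi\!\left(\frac{\mu t + y_0}{\sqrt t}\right)
           - e^{-2 y_0 \mu}\,\Phi\!\left(\frac{\mu t - y_0}{\sqrt t}\right)

is a difference of two nearly equal terms deep in the tail, so it is
evaluated on the log scale via ``scipy.special.log_ndtr``; underflow is
reported as a :class:`~fhtboost.exceptions.NumericalFailure` rather than
silently returning ``-inf``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr, ndtr

from .data import SurvivalData
from .exceptions import DomainError, NumericalFailure

__all__ = [
    "IGFHTParams",
    "fht_pdf",
    "fht_logpdf",
    "fht_cdf",
    "fht_survival",
    "fht_log_survival",
    "prob_never_hit",
    "censored_loglik",
    "grad_mu",
    "grad_eta_y0",
]

_LOG_S_FLOOR = np.log(1e-300)

_SQRT_2PI = np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class IGFHTParams:
    """Parameters of the Wiener first-hitting-time law.

    mu : drift per unit time; any real. Positive drift makes the time
        distribution defective.
    y0 : initial level; strictly positive.
    sigma : diffusion coefficient; fixed at 1 in all model code.
    """

    mu: float
    y0: float
    sigma: float = 1.0

    def __post_init__(self):
        if not np.all(np.asarray(self.y0) > 0):
            raise DomainError("y0 must be strictly positive")
        if not np.all(np.asarray(self.sigma) > 0):
            raise DomainError("sigma must be strictly positive")


def _check_t_y0(t, y0):
    t = np.asarray(t, dtype=float)
    y0 = np.asarray(y0, dtype=float)
    if np.any(t <= 0) or not np.all(np.isfinite(t)):
        raise DomainError("t must be strictly positive and finite")
    if np.any(y0 <= 0) or not np.all(np.isfinite(y0)):
        raise DomainError("y0 must be strictly positive and finite")
    return t, y0


def _unpack(params: IGFHTParams | None, mu, y0):
    if params is not None:
        return params.mu, params.y0
    return mu, y0


def fht_logpdf(t, params: IGFHTParams | None = None, *, mu=None, y0=None):
    """Log-density of the hitting time (sigma = 1); vectorized."""
    mu, y0 = _unpack(params, mu, y0)
    t, y0 = _check_t_y0(t, y0)
    mu = np.asarray(mu, dtype=float)
    return np.log(y0) - 0.5 * np.log(2.0 * np.pi * t**3) - (mu * t + y0) ** 2 / (2.0 * t)


def fht_pdf(t, params: IGFHTParams | None = None, *, mu=None, y0=None):
    """Density y0/sqrt(2 pi t^3) exp(-(mu t + y0)^2 / (2 t)); vectorized."""
    return np.exp(fht_logpdf(t, params, mu=mu, y0=y0))


def fht_cdf(t, params: IGFHTParams | None = None, *, mu=None, y0=None):
    """P(T <= t) = Phi(-(mu t + y0)/sqrt(t)) + exp(-2 y0 mu) Phi((mu t - y0)/sqrt(t)).

    For mu > 0 the limit as t -> inf is exp(-2 y0 mu) < 1 (defective law).
    """
    mu, y0 = _unpack(params, mu, y0)
    t, y0 = _check_t_y0(t, y0)
    mu = np.asarray(mu, dtype=float)
    rt = np.sqrt(t)
    a = (mu * t + y0) / rt
    b = (mu * t - y0) / rt
    # Both terms are nonnegative; the sum is computed on the log scale to
    # survive deep left tails (small t with large y0).
    log_term1 = log_ndtr(-a)
    log_term2 = -2.0 * y0 * mu + log_ndtr(b)
    return np.exp(np.logaddexp(log_term1, log_term2))


def fht_log_survival(t, params: IGFHTParams | None = None, *, mu=None, y0=None,
                     raise_on_underflow: bool = True):
    """log S(t), evaluated cancellation-safely.

    S(t) = Phi(a) - exp(-2 y0 mu) Phi(b) with a = (mu t + y0)/sqrt(t),
    b = (mu t - y0)/sqrt(t); since a > b always, the ratio of the second
    term to the first lies in (0, 1) in exact arithmetic, and
    log S = log Phi(a) + log1p(-ratio). If the ratio reaches 1 in floating
    point the survival mass has underflowed; that is flagged, not hidden.
    """
    mu, y0 = _unpack(params, mu, y0)
    t, y0 = _check_t_y0(t, y0)
    mu = np.asarray(mu, dtype=float)
    rt = np.sqrt(t)
    a = (mu * t + y0) / rt
    b = (mu * t - y0) / rt
    log_ratio = -2.0 * y0 * mu + log_ndtr(b) - log_ndtr(a)
    ratio = np.exp(np.minimum(log_ratio, 0.0))
    with np.errstate(divide="ignore"):
        log_s = log_ndtr(a) + np.log1p(-ratio)
    underflow = ~np.isfinite(log_s) | (log_s < _LOG_S_FLOOR)
    if np.any(underflow):
        if raise_on_underflow:
            raise NumericalFailure(
                "survival probability underflowed to <= 1e-300; "
                "the model has left the representable range",
                quantity="log_survival",
            )
        log_s = np.where(underflow, _LOG_S_FLOOR, log_s)
    return log_s


def fht_survival(t, params: IGFHTParams | None = None, *, mu=None, y0=None):
    """S(t) = 1 - F(t); non-increasing in t.

    For mu > 0 the curve plateaus at the escape probability:
    S(t) -> 1 - exp(-2 y0 mu) > 0 as t -> inf.
    """
    return np.exp(fht_log_survival(t, params, mu=mu, y0=y0, raise_on_underflow=False))


def prob_never_hit(params: IGFHTParams | None = None, *, mu=None, y0=None):
    """P(T = infinity) = 1 - exp(-2 y0 mu) for mu > 0, else 0."""
    mu, y0 = _unpack(params, mu, y0)
    mu = np.asarray(mu, dtype=float)
    y0 = np.asarray(y0, dtype=float)
    if np.any(y0 <= 0):
        raise DomainError("y0 must be strictly positive")
    return np.where(mu > 0, -np.expm1(-2.0 * y0 * np.maximum(mu, 0.0)), 0.0)


def _validate_vectors(data: SurvivalData, mu_vec, y0_vec):
    mu_vec = np.broadcast_to(np.asarray(mu_vec, dtype=float), (data.n,))
    y0_vec = np.broadcast_to(np.asarray(y0_vec, dtype=float), (data.n,))
    if not np.all(np.isfinite(mu_vec)) or not np.all(np.isfinite(y0_vec)):
        raise DomainError("mu and y0 vectors must be finite")
    if np.any(y0_vec <= 0):
        raise DomainError("all y0 values must be strictly positive")
    return mu_vec, y0_vec


def censored_loglik(data: SurvivalData, mu_vec, y0_vec) -> float:
    """Censored log-likelihood: sum_i d_i log f(t_i) + (1 - d_i) log S(t_i).

    Raises :class:`NumericalFailure` if any censored subject's survival
    probability underflows (sigma fixed at 1).
    """
    mu_vec, y0_vec = _validate_vectors(data, mu_vec, y0_vec)
    d = data.event
    t = data.time
    total = 0.0
    if d.any():
        idx = d == 1
        total += float(np.sum(fht_logpdf(t[idx], mu=mu_vec[idx], y0=y0_vec[idx])))
    if (d == 0).any():
        idx = d == 0
        total += float(np.sum(fht_log_survival(t[idx], mu=mu_vec[idx], y0=y0_vec[idx])))
    return total


def _censored_grad_pieces(t, mu, y0):
    """(dlogS/dmu, dlogS/dy0) for censored subjects, elementwise.

    dS/dmu  = sqrt(t) phi(a) + e^{-2 y0 mu} [2 y0 Phi(b) - sqrt(t) phi(b)]
    dS/dy0  = phi(a)/sqrt(t) + e^{-2 y0 mu} [2 mu Phi(b) + phi(b)/sqrt(t)]
    with a = (mu t + y0)/sqrt(t), b = (mu t - y0)/sqrt(t); divide by S.
    Each term is scaled by exp(-log S) on the log scale where possible to
    avoid 0/0 in the deep tail.
    """
    rt = np.sqrt(t)
    a = (mu * t + y0) / rt
    b = (mu * t - y0) / rt
    log_s = fht_log_survival(t, mu=mu, y0=y0)
    e = np.exp(-2.0 * y0 * mu)
    phi_a = np.exp(-0.5 * a * a) / _SQRT_2PI
    phi_b = np.exp(-0.5 * b * b) / _SQRT_2PI
    phi_big_b = ndtr(b)
    inv_s = np.exp(-log_s)
    ds_dmu = rt * phi_a + e * (2.0 * y0 * phi_big_b - rt * phi_b)
    ds_dy0 = phi_a / rt + e * (2.0 * mu * phi_big_b + phi_b / rt)
    return ds_dmu * inv_s, ds_dy0 * inv_s


def grad_mu(data: SurvivalData, mu_vec, y0_vec) -> np.ndarray:
    """Per-subject derivative of the log-likelihood w.r.t. the drift mu_i.

    Uncensored subjects contribute -(mu_i t_i + y0_i); censored subjects
    the derivative of log S.
    """
    mu_vec, y0_vec = _validate_vectors(data, mu_vec, y0_vec)
    t, d = data.time, data.event
    out = np.empty(data.n)
    ev = d == 1
    out[ev] = -(mu_vec[ev] * t[ev] + y0_vec[ev])
    cn = ~ev
    if cn.any():
        dmu, _ = _censored_grad_pieces(t[cn], mu_vec[cn], y0_vec[cn])
        out[cn] = dmu
    return out


def grad_eta_y0(data: SurvivalData, mu_vec, y0_vec) -> np.ndarray:
    """Per-subject derivative w.r.t. the log-level predictor eta_i = log y0_i.

    Chain rule through the log link: y0_i * dl_i/dy0_i. The uncensored
    part of dl/dy0 is 1/y0 - (y0 + mu t)/t.
    """
    mu_vec, y0_vec = _validate_vectors(data, mu_vec, y0_vec)
    t, d = data.time, data.event
    out = np.empty(data.n)
    ev = d == 1
    out[ev] = y0_vec[ev] * (1.0 / y0_vec[ev] - (y0_vec[ev] + mu_vec[ev] * t[ev]) / t[ev])
    cn = ~ev
    if cn.any():
        _, dy0 = _censored_grad_pieces(t[cn], mu_vec[cn], y0_vec[cn])
        out[cn] = y0_vec[cn] * dy0
    return out
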