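"""Synthetic survival data with covariate-dependent hitting times.

The generator draws iid standard-Gaussian covariates, maps them through
the model's own links (identity for the drift, log for the initial
level), samples inverse-Gaussian first-hitting times per subject, and
censors them with independent exponential times. It exists so that every
layer of the package — the likelihood, the boosting path, tuning and
evaluation — can be exercised end to end against a known truth.

``reference_design`` is the low-dimensional illustration scenario:
n = 200 subjects, four independent N(0, 1) covariates c1, c2, g1, g2,
drift mu = -1 - 0.1 c1 + 0.1 c2, level log y0 = 2 + 0.1 g1 + 0.2 g2,
and Exp(rate 0.1) censoring, which censors roughly half the subjects.

Sampling uses the shape/mean parameterization of the inverse Gaussian:
for mu < 0 the hitting time is IG(mean = y0/|mu|, shape = y0^2); for
mu = 0 it is the one-sided stable law y0^2 / chi^2_1; for mu > 0 the
subject escapes with probability 1 - exp(-2 y0 mu) (time = infinity) and
otherwise hits at a time drawn from the mirrored-drift law
IG(y0, -mu) — the conditional distribution given a finite hit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import DesignPair, SurvivalData
from .exceptions import ConfigError, DomainError

__all__ = [
    "SimulationDesign",
    "reference_design",
    "sample_fht_time",
    "simulate_dataset",
    "expected_censoring_fraction",
]


@dataclass
class SimulationDesign:
    """Data-generating truth for one synthetic dataset.

    beta/gamma are the true coefficient vectors, intercept first, so
    their lengths fix the covariate counts p_mu and p_y0. Covariates are
    iid standard Gaussian; the two covariate blocks are disjoint columns
    of one table. Censoring is exponential with rate ``censoring_rate``
    (0 disables it), optionally truncated at ``administrative_time``.
    """

    n: int
    beta: np.ndarray
    gamma: np.ndarray
    censoring_rate: float = 0.0
    administrative_time: float | None = None
    seed: int = 0
    mu_prefix: str = "c"
    y0_prefix: str = "g"

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.n < 1 or self.beta.ndim != 1 or self.gamma.ndim != 1:
            raise ConfigError("invalid simulation design")
        if self.censoring_rate < 0:
            raise ConfigError("censoring_rate must be nonnegative")

    @property
    def p_mu(self) -> int:
        return self.beta.size - 1

    @property
    def p_y0(self) -> int:
        return self.gamma.size - 1


def reference_design(n: int = 200, censoring_rate: float = 0.1,
                     seed: int = 0) -> SimulationDesign:
    """The low-dimensional illustration scenario (see module docstring)."""
    return SimulationDesign(
        n=n,
        beta=np.array([-1.0, -0.1, 0.1]),
        gamma=np.array([2.0, 0.1, 0.2]),
        censoring_rate=censoring_rate,
        seed=seed,
    )


def sample_fht_time(y0, mu, rng: np.random.Generator) -> np.ndarray:
    """Draw first-hitting times; vectorized, may return ``inf``.

    For mu <= 0 the law is proper; for mu > 0 the draw is infinite with
    the escape probability 1 - exp(-2 y0 mu).
    """
    y0 = np.asarray(y0, dtype=float)
    mu = np.asarray(mu, dtype=float)
    y0, mu = np.broadcast_arrays(y0, mu)
    if np.any(y0 <= 0):
        raise DomainError("y0 must be strictly positive")
    out = np.empty(y0.shape)

    neg = mu < 0
    if neg.any():
        lam = y0[neg] ** 2
        mean = y0[neg] / np.abs(mu[neg])
        # scipy's invgauss: mean = m * scale, shape = scale.
        out[neg] = stats.invgauss.rvs(mean / lam, scale=lam, random_state=rng)

    zero = mu == 0
    if zero.any():
        # Drift-free hitting time: y0^2 / chi^2_1 (a one-sided stable law).
        z = rng.standard_normal(zero.sum())
        out[zero] = y0[zero] ** 2 / z**2

    pos = mu > 0
    if pos.any():
        escape = rng.random(pos.sum()) > np.exp(-2.0 * y0[pos] * mu[pos])
        lam = y0[pos] ** 2
        mean = y0[pos] / mu[pos]
        finite_draw = stats.invgauss.rvs(mean / lam, scale=lam, random_state=rng)
        out[pos] = np.where(escape, np.inf, finite_draw)

    return out


def simulate_dataset(design: SimulationDesign):
    """Generate one dataset: ``(SurvivalData, DesignPair, truth)``.

    ``truth`` is a DataFrame holding the latent event time T, censoring
    time C and per-subject (mu, y0) for oracle checks. Infinite event
    times (possible when the design allows positive drift) must be
    censorable: they require ``censoring_rate > 0`` or an administrative
    time, otherwise the observed time would be infinite.
    """
    rng = np.random.default_rng(design.seed)
    X_mu = rng.standard_normal((design.n, design.p_mu))
    X_y0 = rng.standard_normal((design.n, design.p_y0))
    mu = design.beta[0] + X_mu @ design.beta[1:]
    y0 = np.exp(design.gamma[0] + X_y0 @ design.gamma[1:])

    T = sample_fht_time(y0, mu, rng)

    C = np.full(design.n, np.inf)
    if design.censoring_rate > 0:
        C = rng.exponential(1.0 / design.censoring_rate, design.n)
    if design.administrative_time is not None:
        C = np.minimum(C, design.administrative_time)
    if np.any(np.isinf(T) & np.isinf(C)):
        raise ConfigError(
            "design permits infinite event times but has no censoring; "
            "set censoring_rate > 0 or an administrative_time")

    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    data = SurvivalData(time, event)
    mu_names = [f"{design.mu_prefix}{j + 1}" for j in range(design.p_mu)]
    y0_names = [f"{design.y0_prefix}{j + 1}" for j in range(design.p_y0)]
    designs = DesignPair(X_mu, X_y0, mu_names, y0_names)
    truth = pd.DataFrame({"T": T, "C": C, "mu": mu, "y0": y0})
    return data, designs, truth


def expected_censoring_fraction(design: SimulationDesign, reps: int = 200_000):
    """Monte-Carlo P(C < T) under the design, with its standard error.

    Draws ``reps`` independent subjects from the design (fresh covariates
    each, seeded from ``design.seed``) and returns ``(estimate, se)``.
    """
    if reps < 1:
        raise ConfigError("reps must be >= 1")
    if design.censoring_rate <= 0 and design.administrative_time is None:
        return 0.0, 0.0
    rng = np.random.default_rng(design.seed)
    censored = 0
    chunk = 500_000
    done = 0
    while done < reps:
        k = min(chunk, reps - done)
        Xm = rng.standard_normal((k, design.p_mu))
        Xy = rng.standard_normal((k, design.p_y0))
        mu = design.beta[0] + Xm @ design.beta[1:]
        y0 = np.exp(design.gamma[0] + Xy @ design.gamma[1:])
        T = sample_fht_time(y0, mu, rng)
        C = np.full(k, np.inf)
        if design.censoring_rate > 0:
            C = rng.exponential(1.0 / design.censoring_rate, k)
        if design.administrative_time is not None:
            C = np.minimum(C, design.administrative_time)
        censored += int(np.sum(C < T))
        done += k
    p = censored / reps
    se = float(np.sqrt(p * (1.0 - p) / reps))
    return p, se
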