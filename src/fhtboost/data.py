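"""Core data containers: survival outcomes, covariate designs, coefficients.

The model has two regression equations, one per distribution parameter:
the drift mu uses an identity link, mu_i = beta0 + sum_j beta_j x_ij, and
the initial health level y0 uses a log link, log y0_i = gamma0 +
sum_j gamma_j x_ij. Each equation may use its own covariate matrix, which
is how low-dimensional clinical and high-dimensional molecular blocks are
integrated without weighting schemes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DomainError, SchemaError

__all__ = ["SurvivalData", "DesignPair", "CoefficientState"]


@dataclass(frozen=True)
class SurvivalData:
    """Right-censored survival outcomes.

    Parameters
    ----------
    time
        Observed times, strictly positive and finite.
    event
        Event indicators: 1 = event observed, 0 = right-censored.
    ids
        Optional subject identifiers (defaults to 0..n-1).
    """

    time: np.ndarray
    event: np.ndarray
    ids: np.ndarray = None

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event)
        if time.ndim != 1 or event.ndim != 1 or time.shape != event.shape:
            raise SchemaError("time and event must be 1-d arrays of equal length")
        if not np.all(np.isfinite(time)) or np.any(time <= 0):
            raise DomainError("all observed times must be strictly positive and finite")
        if not np.isin(event, (0, 1)).all():
            raise SchemaError("event indicators must be 0 (censored) or 1 (event)")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event.astype(np.int64))
        ids = self.ids if self.ids is not None else np.arange(time.size)
        object.__setattr__(self, "ids", np.asarray(ids))

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, index) -> "SurvivalData":
        return SurvivalData(self.time[index], self.event[index], self.ids[index])

    def concat(self, other: "SurvivalData") -> "SurvivalData":
        return SurvivalData(
            np.concatenate([self.time, other.time]),
            np.concatenate([self.event, other.event]),
            np.concatenate([self.ids, other.ids]),
        )


class DesignPair:
    """The two covariate matrices, one per distribution parameter.

    ``X_mu`` feeds the drift regression, ``X_y0`` the initial-level
    regression. They may be the same matrix, share columns, or be disjoint
    blocks (the clinical/molecular split). Either may have zero columns,
    in which case the corresponding parameter is intercept-only.
    """

    def __init__(self, X_mu, X_y0, mu_names=None, y0_names=None):
        self.X_mu, self.mu_names = self._coerce(X_mu, mu_names, "mu")
        self.X_y0, self.y0_names = self._coerce(X_y0, y0_names, "y0")
        if self.X_mu.shape[0] != self.X_y0.shape[0]:
            raise SchemaError("X_mu and X_y0 must have the same number of rows")

    @staticmethod
    def _coerce(X, names, side):
        if isinstance(X, pd.DataFrame):
            names = list(map(str, X.columns))
            X = X.to_numpy(dtype=float)
        else:
            X = np.atleast_2d(np.asarray(X, dtype=float))
            if X.size == 0:
                X = X.reshape(X.shape[0] if X.ndim == 2 else 0, 0)
            if names is None:
                names = [f"{side}_x{j + 1}" for j in range(X.shape[1])]
            names = list(map(str, names))
        if len(names) != X.shape[1]:
            raise SchemaError(f"{side}: {len(names)} names for {X.shape[1]} columns")
        if len(set(names)) != len(names):
            raise SchemaError(f"{side}: duplicate column names")
        if X.size and not np.all(np.isfinite(X)):
            raise SchemaError(f"{side}: covariate matrix contains non-finite values")
        return X, names

    @property
    def n(self) -> int:
        return self.X_mu.shape[0]

    @property
    def p_mu(self) -> int:
        return self.X_mu.shape[1]

    @property
    def p_y0(self) -> int:
        return self.X_y0.shape[1]

    def subset(self, index) -> "DesignPair":
        return DesignPair(self.X_mu[index], self.X_y0[index],
                          self.mu_names, self.y0_names)


@dataclass
class CoefficientState:
    """Regression coefficients for both parameters, intercepts first.

    ``beta`` has length p_mu + 1 (drift side, identity link); ``gamma``
    has length p_y0 + 1 (initial-level side, log link).
    """

    beta: np.ndarray
    gamma: np.ndarray

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float).copy()
        self.gamma = np.asarray(self.gamma, dtype=float).copy()

    @classmethod
    def null(cls, beta0: float, gamma0: float, p_mu: int, p_y0: int):
        beta = np.zeros(p_mu + 1)
        gamma = np.zeros(p_y0 + 1)
        beta[0], gamma[0] = beta0, gamma0
        return cls(beta, gamma)

    def copy(self) -> "CoefficientState":
        return CoefficientState(self.beta, self.gamma)

    def linear_predictors(self, designs: DesignPair):
        """Per-subject (mu_i, eta_i) where eta = log y0."""
        mu = self.beta[0] + designs.X_mu @ self.beta[1:]
        eta = self.gamma[0] + designs.X_y0 @ self.gamma[1:]
        return mu, eta
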