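"""User-facing model object: fit, predict, serialize.

A fitted :class:`FHTBoostModel` stores the coefficient vectors of both
regression equations together with the column names they were trained
on, so prediction inputs are matched by name, never by position. The
clinical/molecular block assignment is whatever :class:`DesignPair` the
caller provided: putting the clinical table in ``X_mu`` and the
molecular matrix in ``X_y0`` yields the "clinical drift" configuration,
and swapping them yields "clinical level". The assignment must be chosen
by the analyst in advance; both are legitimate and comparable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import __about__
from .boosting import BoostingConfig, BoostingTrace, boost
from .data import CoefficientState, DesignPair, SurvivalData
from .exceptions import FittingError, NumericalFailure, SchemaError
from .distributions import fht_survival

__all__ = ["FHTBoostModel", "fit"]


@dataclass
class FHTBoostModel:
    """A fitted boosting first-hitting-time model."""

    state: CoefficientState
    mu_names: list
    y0_names: list
    config: BoostingConfig
    trace: BoostingTrace | None = None
    train_loss: float | None = None

    # -- prediction ------------------------------------------------------

    def _matrix(self, X_new, names) -> np.ndarray:
        if isinstance(X_new, pd.DataFrame):
            missing = [c for c in names if c not in X_new.columns]
            if missing:
                raise SchemaError(f"missing covariate column(s): {missing}")
            return X_new[names].to_numpy(dtype=float) if names else np.zeros((len(X_new), 0))
        X = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X.shape[1] != len(names):
            raise SchemaError(
                f"expected {len(names)} columns ({names}), got {X.shape[1]}")
        return X

    def predict_params(self, X_mu_new, X_y0_new=None):
        """Per-subject (mu_hat, y0_hat).

        With a single DataFrame argument containing all training columns,
        both sides are extracted from it by name.
        """
        if X_y0_new is None:
            X_y0_new = X_mu_new
        Xm = self._matrix(X_mu_new, self.mu_names)
        Xy = self._matrix(X_y0_new, self.y0_names)
        if Xm.shape[0] != Xy.shape[0]:
            raise SchemaError("covariate tables disagree on the number of rows")
        mu = self.state.beta[0] + Xm @ self.state.beta[1:]
        y0 = np.exp(self.state.gamma[0] + Xy @ self.state.gamma[1:])
        return mu, y0

    def predict_survival(self, X_mu_new, X_y0_new=None, times=None) -> pd.DataFrame:
        """Predicted survival curves S_i(t_k) on a sorted time grid.

        Returns a DataFrame with one row per subject and one column per
        time point. Rows are non-increasing; for subjects with positive
        predicted drift the curve plateaus at the escape probability.
        """
        times = np.asarray(times, dtype=float)
        if times.ndim != 1 or times.size == 0 or np.any(np.diff(times) < 0):
            raise SchemaError("times must be a non-empty ascending 1-d grid")
        mu, y0 = self.predict_params(X_mu_new, X_y0_new)
        S = fht_survival(times[None, :], mu=mu[:, None], y0=y0[:, None])
        return pd.DataFrame(S, columns=times)

    # -- serialization ---------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "format": "fhtboost-model",
            "version": __about__.__version__,
            "beta": self.state.beta.tolist(),
            "gamma": self.state.gamma.tolist(),
            "mu_names": list(self.mu_names),
            "y0_names": list(self.y0_names),
            "config": asdict(self.config),
            "train_loss": self.train_loss,
        }
        return json.dumps(doc, indent=1)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "FHTBoostModel":
        doc = json.loads(text)
        if doc.get("format") != "fhtboost-model":
            raise SchemaError("not an fhtboost model document")
        return cls(
            state=CoefficientState(np.array(doc["beta"]), np.array(doc["gamma"])),
            mu_names=list(doc["mu_names"]),
            y0_names=list(doc["y0_names"]),
            config=BoostingConfig(**doc["config"]),
            train_loss=doc.get("train_loss"),
        )

    @classmethod
    def load(cls, path) -> "FHTBoostModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def fit(data: SurvivalData, designs: DesignPair,
        config: BoostingConfig) -> FHTBoostModel:
    """Fit a boosting first-hitting-time model.

    Dispatches to the cyclical or non-cyclical engine according to
    ``config.variant``. Numerical failures propagate with a remediation
    hint (retry with a smaller nu, e.g. via
    :func:`fhtboost.boosting.boost_with_retry`).
    """
    if data.n != designs.n:
        raise SchemaError("survival data and designs disagree on subject count")
    try:
        state, trace = boost(data, designs, config)
    except NumericalFailure as err:
        raise FittingError(
            f"boosting failed at iteration {err.iteration}: {err}; "
            "retry with a smaller step size nu", detail=err) from err
    return FHTBoostModel(state=state, mu_names=designs.mu_names,
                         y0_names=designs.y0_names, config=config,
                         trace=trace, train_loss=trace.losses[-1])
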