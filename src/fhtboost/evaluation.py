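"""Prediction-accuracy machinery: Kaplan-Meier, IPCW Brier score, IBS.

The Brier score at a horizon t* is the mean squared difference between
the event-status indicator 1{T_i > t*} and the predicted survival
probability, reweighted by the inverse of the censoring distribution's
Kaplan-Meier estimate G (Graf-style inverse-probability-of-censoring
weighting):

* subjects with an observed event before t*: weight 1 / G(T_i-),
* subjects still under observation at t*:    weight 1 / G(t*),
* subjects censored before t*:               weight 0.

G is estimated on the *training* set so that no test information leaks
into the weights. The Integrated Brier Score averages the Brier curve
over time (trapezoidal rule divided by the interval length), by
convention up to the penultimate distinct observed time of the test set,
where the weights are still stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .data import SurvivalData
from .exceptions import ConfigError, DomainError

__all__ = [
    "StepFunction",
    "km_estimator",
    "brier_score",
    "brier_curve",
    "integrated_brier_score",
    "calibration_table",
]


@dataclass(frozen=True)
class StepFunction:
    """Right-continuous step function with value 1 before the first jump.

    The canonical representation of a Kaplan-Meier survival estimate:
    ``__call__`` evaluates S(t), ``left_limit`` evaluates S(t-).
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape or np.any(np.diff(t) <= 0):
            raise ConfigError("jump times must be 1-d, strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        vals = np.concatenate([[1.0], self.values])
        return vals[idx]

    def left_limit(self, t):
        """S(t-): the value just before t."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="left")
        vals = np.concatenate([[1.0], self.values])
        return vals[idx]


def km_estimator(data: SurvivalData, target: str = "event") -> StepFunction:
    """Product-limit estimator of the event or censoring distribution.

    ``target="censoring"`` flips the event indicator, yielding the
    reverse Kaplan-Meier estimate G used for IPCW weights. All-censored
    data (or no censoring, for the censoring target) give the constant-1
    function.
    """
    if target not in ("event", "censoring"):
        raise ConfigError("target must be 'event' or 'censoring'")
    d = data.event if target == "event" else 1 - data.event
    if d.sum() == 0:
        return StepFunction(np.array([np.inf]), np.array([1.0]))
    kmf = KaplanMeierFitter()
    kmf.fit(data.time, d)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    values = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = times > 0  # lifelines inserts t=0 with S=1, already implied
    return StepFunction(times[keep], values[keep])


def brier_score(t_star: float, predicted, test: SurvivalData,
                censor_km: StepFunction) -> float:
    """IPCW Brier score at horizon ``t_star``.

    ``predicted`` holds each test subject's predicted S(t_star);
    ``censor_km`` is the censoring-distribution Kaplan-Meier estimate
    from the training data. Raises if a required weight 1/G is undefined
    (G = 0 at a needed time).
    """
    predicted = np.asarray(predicted, dtype=float)
    if predicted.shape != (test.n,):
        raise ConfigError("predicted must hold one S(t*) per test subject")
    t, d = test.time, test.event
    event_before = (t <= t_star) & (d == 1)
    at_risk = t > t_star
    weights = np.zeros(test.n)
    if event_before.any():
        g = censor_km.left_limit(t[event_before])
        if np.any(g <= 0):
            bad = t[event_before][g <= 0].min()
            raise DomainError(f"censoring survival is 0 at t={bad:g}-; "
                              "IPCW weight undefined")
        weights[event_before] = 1.0 / g
    if at_risk.any():
        g_star = float(censor_km(t_star))
        if g_star <= 0:
            raise DomainError(f"censoring survival is 0 at t={t_star:g}; "
                              "IPCW weight undefined")
        weights[at_risk] = 1.0 / g_star
    resid = (at_risk.astype(float) - predicted) ** 2
    return float(np.mean(weights * resid))


def brier_curve(times, predicted_matrix, test: SurvivalData,
                censor_km: StepFunction) -> pd.DataFrame:
    """Brier score at each grid time; column k of ``predicted_matrix``
    holds the predicted S at ``times[k]``."""
    times = np.asarray(times, dtype=float)
    P = np.asarray(predicted_matrix, dtype=float)
    if P.shape != (test.n, times.size):
        raise ConfigError("predicted_matrix must be n_test x n_times")
    scores = [brier_score(tk, P[:, k], test, censor_km)
              for k, tk in enumerate(times)]
    return pd.DataFrame({"time": times, "brier": scores})


def default_eval_times(test: SurvivalData) -> np.ndarray:
    """Distinct observed test times up to the penultimate one."""
    distinct = np.unique(test.time)
    if distinct.size < 2:
        raise ConfigError("need at least 2 distinct observed times")
    return distinct[:-1]


def integrated_brier_score(times, scores) -> float:
    """Time-averaged trapezoidal integral of a Brier curve.

    Dividing by the integration length makes the score comparable across
    datasets with different follow-up; a constant curve integrates to its
    own value.
    """
    times = np.asarray(times, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if times.size < 2:
        raise ConfigError("need at least 2 grid points to integrate")
    if np.any(np.diff(times) <= 0):
        raise ConfigError("time grid must be strictly increasing")
    length = times[-1] - times[0]
    return float(np.trapezoid(scores, times) / length)


def calibration_table(t_star: float, predicted, test: SurvivalData,
                      bins: int = 10) -> pd.DataFrame:
    """Observed (KM) vs mean predicted survival within quantile bins.

    Subjects are grouped into ``bins`` quantile bins of predicted
    S(t_star); within each bin the observed survival at t_star is the
    Kaplan-Meier estimate of the bin members. Bins that receive no
    subjects (possible with heavily tied predictions) are reported with
    missing values.
    """
    if bins < 1:
        raise ConfigError("bins must be >= 1")
    predicted = np.asarray(predicted, dtype=float)
    if predicted.shape != (test.n,):
        raise ConfigError("predicted must hold one S(t*) per test subject")
    edges = np.quantile(predicted, np.linspace(0, 1, bins + 1))
    edges = np.unique(edges)
    # assign: right-closed bins; ties collapse into one bin
    n_real = max(len(edges) - 1, 1)
    if len(edges) == 1:
        idx = np.zeros(test.n, dtype=int)
    else:
        idx = np.clip(np.searchsorted(edges, predicted, side="right") - 1,
                      0, n_real - 1)
    rows = []
    for b in range(bins):
        if b >= n_real:
            rows.append({"bin": b, "mean_predicted": np.nan,
                         "observed_km": np.nan, "count": 0})
            continue
        members = idx == b
        count = int(members.sum())
        if count == 0:
            rows.append({"bin": b, "mean_predicted": np.nan,
                         "observed_km": np.nan, "count": 0})
            continue
        sub = test.subset(members)
        km = km_estimator(sub, "event")
        rows.append({
            "bin": b,
            "mean_predicted": float(predicted[members].mean()),
            "observed_km": float(km(t_star)),
            "count": count,
        })
    return pd.DataFrame(rows)
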