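"""Cross-validated choice of the boosting stopping iteration(s).

The number of boosting iterations is the model's regularization
parameter. For the cyclical variant there are two of them, one per
distribution parameter, searched over a log-spaced grid (20 x 20 on
[1, 200] by default); for the non-cyclical variant a single stopping
value is searched over every integer up to the maximum. The held-out
risk is the negative censored log-likelihood of the held-out fold,
summed over folds.

Grid points are evaluated *path-wise*: for a fixed fold, all models
along an increasing stopping value are snapshots of one boosting run,
never separate refits. For the two-dimensional cyclical grid each run
pins one coordinate at a grid value and lets the other grow to the
maximum, so a truncation of the run at iteration m is exactly the fit
with the larger coordinate equal to m. After the grid search the drift
coordinate is refined over every integer up to the maximum, holding the
level coordinate at its best grid value, which is cheap because it is a
single run per fold.

One fixed fold split (a function of n, K and the seed alone) is shared
by every grid point, so risks are comparable across the surface. Because
the split can materially affect the chosen stopping value, an optional
repeated-CV mode averages the risk surface over several independent
splits.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .boosting import BoostingConfig, BoostingTrace, boost
from .data import DesignPair, SurvivalData
from .distributions import censored_loglik
from .exceptions import ConfigError, FittingError
from .model import FHTBoostModel, fit

__all__ = ["CVPlan", "CVResult", "make_grid_1d", "make_grid", "make_folds", "cv_select"]


@dataclass(frozen=True)
class CVPlan:
    """Cross-validation settings.

    K : fold count (default 10).
    max_mstop : largest stopping value considered (default 200).
    grid_points : per-coordinate size of the log-spaced grid (default 20).
    repeats : number of independent fold splits to average over.
    """

    K: int = 10
    max_mstop: int = 200
    grid_points: int = 20
    repeats: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.K < 2:
            raise ConfigError("K must be >= 2")
        if self.repeats < 1:
            raise ConfigError("repeats must be >= 1")


@dataclass
class CVResult:
    """Outcome of :func:`cv_select`."""

    chosen: tuple
    risk_surface: pd.DataFrame
    model: FHTBoostModel


def make_grid_1d(max_mstop: int, points: int) -> np.ndarray:
    """``points`` distinct integers log-spaced on [1, max_mstop].

    The un-rounded values have a constant consecutive ratio; rounding
    collisions at the small end are resolved by bumping each duplicate to
    the next unused integer, so the grid always starts at 1, ends at
    max_mstop and has exactly ``points`` members.
    """
    if points < 2 or max_mstop < points:
        raise ConfigError("need points >= 2 and max_mstop >= points")
    raw = np.exp(np.linspace(0.0, np.log(max_mstop), points))
    vals = []
    prev = 0
    for v in raw:
        g = max(int(np.rint(v)), prev + 1)
        vals.append(g)
        prev = g
    if vals[-1] > max_mstop:  # cannot happen for max_mstop >= points, kept defensive
        raise ConfigError("grid exceeds max_mstop")
    return np.asarray(vals, dtype=int)


def make_grid(max_mstop: int = 200, points: int = 20) -> list[tuple[int, int]]:
    """Cartesian product of the 1-d log grid with itself:
    candidate (mstop_mu, mstop_y0) pairs for the cyclical variant."""
    g = make_grid_1d(max_mstop, points)
    return [(int(a), int(b)) for a in g for b in g]


def make_folds(n: int, K: int, seed: int, events: np.ndarray | None = None,
               max_retries: int = 20) -> np.ndarray:
    """Random fold assignment 0..K-1 per subject, a function of (n, K, seed).

    If ``events`` is given, re-randomizes (bounded retries, deterministic
    sequence) until every training part — i.e. the complement of each
    fold — contains at least one event.
    """
    if K > n:
        raise ConfigError("more folds than subjects")
    for attempt in range(max_retries):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        assignment = rng.permutation(n) % K
        if events is None:
            return assignment
        ok = all((events[assignment != k]).sum() >= 1 for k in range(K))
        if ok:
            return assignment
    raise FittingError(
        f"could not build {K} folds whose training parts all contain an event "
        f"after {max_retries} re-randomizations")


def _heldout_losses(trace: BoostingTrace, test_data: SurvivalData,
                    test_designs: DesignPair, iterations) -> dict[int, float]:
    """Negative held-out log-likelihood of trace snapshots."""
    out = {}
    for m in iterations:
        state = trace.snapshots[m]
        mu, eta = state.linear_predictors(test_designs)
        try:
            out[m] = -censored_loglik(test_data, mu, np.exp(eta))
        except Exception:
            out[m] = np.inf
    return out


def _cv_cyclical(data, designs, config, plan, folds):
    grid = make_grid_1d(plan.max_mstop, plan.grid_points)
    M = plan.max_mstop
    records = []  # (mstop_mu, mstop_y0, fold, loss)
    for k in np.unique(folds):
        train_idx = folds != k
        test_idx = ~train_idx
        d_tr, d_te = data.subset(train_idx), data.subset(test_idx)
        x_tr, x_te = designs.subset(train_idx), designs.subset(test_idx)
        # Runs pinning the level coordinate: truncation at iteration m >= v
        # is the fit (mstop_mu=m, mstop_y0=v).
        for v in grid:
            cfg = replace(config, variant="cyclical", mstop_mu=M, mstop_y0=int(v))
            _, trace = boost(d_tr, x_tr, cfg)
            wanted = [int(m) for m in grid if m >= v]
            losses = _heldout_losses(trace, d_te, x_te, wanted)
            records += [(m, int(v), int(k), losses[m]) for m in wanted]
            if v == grid[-1]:
                continue
            # Runs pinning the drift coordinate cover the m_mu < m_y0 half.
            cfg = replace(config, variant="cyclical", mstop_mu=int(v), mstop_y0=M)
            _, trace = boost(d_tr, x_tr, cfg)
            wanted = [int(m) for m in grid if m > v]
            losses = _heldout_losses(trace, d_te, x_te, wanted)
            records += [(int(v), m, int(k), losses[m]) for m in wanted]
    df = pd.DataFrame(records, columns=["mstop_mu", "mstop_y0", "fold", "heldout_loss"])
    agg = df.groupby(["mstop_mu", "mstop_y0"], as_index=False)["heldout_loss"].sum()
    best = agg.loc[agg["heldout_loss"].idxmin()]
    best_my0 = int(best["mstop_y0"])
    # 1-d refinement of the drift coordinate at the best level coordinate:
    # one run per fold, held-out loss at every iteration m >= best_my0
    # (below it the truncation changes both coordinates, so the grid rows
    # already on file are authoritative there).
    refine = []
    for k in np.unique(folds):
        train_idx = folds != k
        d_tr, d_te = data.subset(train_idx), data.subset(~train_idx)
        x_tr, x_te = designs.subset(train_idx), designs.subset(~train_idx)
        cfg = replace(config, variant="cyclical", mstop_mu=M, mstop_y0=best_my0)
        _, trace = boost(d_tr, x_tr, cfg)
        wanted = list(range(best_my0, M + 1))
        losses = _heldout_losses(trace, d_te, x_te, wanted)
        refine += [(m, best_my0, int(k), losses[m]) for m in wanted]
    refine_df = pd.DataFrame(refine, columns=df.columns)
    all_df = pd.concat([df, refine_df], ignore_index=True).drop_duplicates(
        subset=["mstop_mu", "mstop_y0", "fold"])
    agg = all_df.groupby(["mstop_mu", "mstop_y0"], as_index=False)["heldout_loss"].sum()
    best = agg.loc[agg["heldout_loss"].idxmin()]
    chosen = (int(best["mstop_mu"]), int(best["mstop_y0"]))
    return chosen, all_df


def _cv_noncyclical(data, designs, config, plan, folds):
    M = plan.max_mstop
    records = []
    for k in np.unique(folds):
        train_idx = folds != k
        d_tr, d_te = data.subset(train_idx), data.subset(~train_idx)
        x_tr, x_te = designs.subset(train_idx), designs.subset(~train_idx)
        cfg = replace(config, variant="noncyclical", mstop=M)
        _, trace = boost(d_tr, x_tr, cfg)
        losses = _heldout_losses(trace, d_te, x_te, range(1, M + 1))
        records += [(m, int(k), losses[m]) for m in range(1, M + 1)]
    df = pd.DataFrame(records, columns=["mstop", "fold", "heldout_loss"])
    agg = df.groupby("mstop", as_index=False)["heldout_loss"].sum()
    best = agg.loc[agg["heldout_loss"].idxmin()]
    return (int(best["mstop"]),), df


def cv_select(data: SurvivalData, designs: DesignPair, config: BoostingConfig,
              plan: CVPlan) -> CVResult:
    """Choose the stopping iteration(s) by K-fold cross-validation.

    Returns the minimizing stopping value(s), the full per-fold risk
    table, and the final model refit on all data at the chosen values.
    With ``plan.repeats > 1`` the fold split is redrawn that many times
    and risks are averaged before minimizing.
    """
    surfaces = []
    chosen_candidates = []
    for r in range(plan.repeats):
        folds = make_folds(data.n, plan.K, plan.seed + r, events=data.event)
        if config.variant == "cyclical":
            chosen, df = _cv_cyclical(data, designs, config, plan, folds)
        else:
            chosen, df = _cv_noncyclical(data, designs, config, plan, folds)
        df = df.assign(repeat=r)
        surfaces.append(df)
        chosen_candidates.append(chosen)
    surface = pd.concat(surfaces, ignore_index=True)
    if plan.repeats > 1:
        keys = [c for c in ("mstop_mu", "mstop_y0", "mstop") if c in surface.columns]
        per_split = surface.groupby(keys + ["repeat"], as_index=False)["heldout_loss"].sum()
        counts = per_split.groupby(keys).size()
        complete = counts[counts == plan.repeats].index
        agg = per_split.set_index(keys).loc[complete].groupby(keys)["heldout_loss"].mean()
        chosen = tuple(int(v) for v in np.atleast_1d(agg.idxmin()))
    else:
        chosen = chosen_candidates[0]
    if config.variant == "cyclical":
        final_cfg = replace(config, mstop_mu=chosen[0], mstop_y0=chosen[1])
    else:
        final_cfg = replace(config, mstop=chosen[0])
    model = fit(data, designs, final_cfg)
    return CVResult(chosen=chosen, risk_surface=surface, model=model)
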