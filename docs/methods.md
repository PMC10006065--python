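# Methods

## Model

The event time is the first passage of a latent Wiener process
`Y(t) = y0 + mu t + sigma W(t)` through 0, starting at `y0 > 0`. The
hitting time is inverse-Gaussian with density
`f(t) = y0 (2 pi sigma^2 t^3)^(-1/2) exp{-(mu t + y0)^2 / (2 sigma^2 t)}`
and survival
`S(t) = Phi((mu t + y0)/sqrt(sigma^2 t)) - exp(-2 y0 mu / sigma^2) Phi((mu t - y0)/sqrt(sigma^2 t))`.
Density and survival depend on `(mu, y0, sigma)` only through
`mu/sigma` and `y0/sigma`, so `sigma` is identically 1 in all model
code; the field exists on `IGFHTParams` for documentation and testing
only. For `mu > 0` the law is defective with escape mass
`P(T = inf) = 1 - exp(-2 y0 mu)`; for `mu <= 0` hitting is almost sure
and `prob_never_hit` returns exactly 0 (the natural extension of the
escape formula, which is usually quoted for positive drift only).

Right censoring enters through the log-likelihood
`l = sum_i d_i log f(t_i) + (1 - d_i) log S(t_i)`. Covariates act
through two linear predictors: `mu = x' beta` (identity link — drift
may have either sign) and `log y0 = x' gamma` (log link — the level
must stay positive). The two design matrices may coincide, overlap, or
be disjoint blocks; the model stays identifiable in all three cases.

## Gradients

The boosting engine consumes per-subject derivatives of `l` with
respect to `mu_i` and to the *level predictor* `eta_i = log y0_i`. Both
are implemented as analytic derivatives of the log-likelihood:

* uncensored: `dl/dmu = -(mu t + y0)`,
  `dl/dy0 = 1/y0 - (y0 + mu t)/t`;
* censored: the corresponding derivatives of `log S`, e.g.
  `dS/dmu = sqrt(t) phi(a) + e^{-2 y0 mu} (2 y0 Phi(b) - sqrt(t) phi(b))`
  with `a = (mu t + y0)/sqrt(t)`, `b = (mu t - y0)/sqrt(t)`, divided
  by `S`.

The level-side gradient carries the chain-rule factor `y0` from the log
link, because the base learners fit and update coefficients on the
predictor scale. Both gradients are verified against central finite
differences of the log-likelihood (relative error `1e-6` over a
thousand randomized censored and uncensored configurations) rather than
against any transcribed closed form — the likelihood is the ground
truth and its derivative is what the descent direction must be.

## Numerical safety

`S(t)` is a difference of two nearly equal terms whenever the censored
observation sits deep in the distribution's tail. It is computed as
`log S = log Phi(a) + log1p(-exp(-2 y0 mu + log Phi(b) - log Phi(a)))`
using `log_ndtr`; the inner ratio is below 1 in exact arithmetic
(`a > b` always), so a ratio reaching 1 in floating point means the
survival mass has underflowed. That event raises a structured
`NumericalFailure` (iteration index and offending quantity attached)
instead of silently propagating `-inf`: likelihood-based FHT fitting is
known to fail in flat or rough regions of the objective, and failures
must be visible and actionable. The standard remediation — rerun with
`nu/10` and 10x the iterations — is packaged as `boost_with_retry`.
`S` values are floored at `1e-300` where a caller asks for
non-raising evaluation.

## Boosting

Iteration 0 is the null model: both intercepts set to the constant-
parameter maximum-likelihood estimate, obtained by L-BFGS-B on
`(mu, log y0)` with analytic gradients and a moment-guided start
(`mu = -1`, `y0 = mean observed time`, since the proper law's mean is
`y0/|mu|`), with two fallback starts. All other coefficients start at 0.

Each component-wise step fits `u ~ a + b x_j` by simple least squares
for every candidate column, scales `(a, b)` by `nu`, and selects the
column whose tentative update minimizes the *achieved training loss*
(ties to the smallest column index, for determinism). Candidate losses
are evaluated for all columns in one vectorized pass, which is what
keeps `p = 1000` tuning runs affordable. A cheaper selection rule —
smallest residual sum of squares of the base-learner fit, the classic
component-wise criterion — is available as `selection_rule =
"gradient_rss"`. Base learners include their own intercept, so the
intercepts move together with whichever covariate is selected at every
iteration. Zero-variance columns get a zero slope and are never
preferred over a loss-reducing column.

The cyclical variant updates the drift first and then the level within
the same iteration, recomputing the level gradient after the drift
update (sequential, not parallel). Its two stopping values can differ,
so late iterations may update only one side. The non-cyclical variant
computes both candidates at the current state and applies the one with
the lower resulting loss (ties favour the drift), so one `mstop`
governs the path.

Covariates are *not* standardized by default; an opt-in flag scales
columns to unit variance during fitting and reports coefficients on the
original scale. Datasets with zero events are rejected at
initialization. `nu` defaults to 0.1 everywhere and is deliberately not
tuned.

## Tuning

Held-out risk is the negative censored log-likelihood of the held-out
fold, summed over folds — the direct analogue of cross-validated
partial likelihood for Cox boosting. Defaults: K = 10 folds, maximum
200 iterations, a 20 x 20 grid of `(mstop_mu, mstop_y0)` log-spaced on
[1, 200] for the cyclical variant (rounding collisions at the small end
are bumped to the next unused integer so the grid really has 20
distinct values per axis), and every integer in [1, 200] for the
non-cyclical variant.

Grid evaluation is path-based: for a fixed fold, one boosting run with
one coordinate pinned at a grid value `v` and the other allowed to grow
to the maximum yields — by truncation at iteration m — every fit with
the free coordinate equal to `m >= v`. Two such run families cover the
whole grid without any refit. After the grid optimum is found, the
drift coordinate is refined over every integer `m >= best mstop_y0`
using one additional run per fold (below `best mstop_y0` a truncation
would alter both coordinates, and the grid rows already cover that
region). One fixed fold split, a deterministic function of
`(n, K, seed)`, is shared by all grid points so risks are comparable;
fold splits whose training parts lack events are re-randomized a
bounded, deterministic number of times. Because the specific split can
influence the chosen stopping value noticeably, `CVPlan(repeats=R)`
averages the risk surface over R independent splits before minimizing.
The final model is refit on all data at the chosen values.

## Evaluation

The Brier score at horizon `t*` is
`mean_i w_i (1{T_i > t*} - S_hat_i(t*))^2` with IPCW weights
`w = 1/G(T_i-)` for subjects with an event before `t*`, `1/G(t*)` for
subjects under observation at `t*`, and 0 for subjects censored before
`t*`. `G` is the reverse Kaplan-Meier estimate of the censoring
distribution computed on the **training** set, so no test information
enters the weights. With no censoring the score reduces exactly to the
mean squared error against the status indicator. The Integrated Brier
Score is the trapezoidal integral of the Brier curve over the distinct
observed test times up to the penultimate one, divided by the interval
length; time-averaging makes the value comparable across datasets and
gives a constant curve its own value (an uninformative constant-0.5
predictor scores 0.25). Calibration tables group subjects into quantile
bins (deciles by default) of predicted `S(t*)` and compare the bin's
mean prediction with the within-bin Kaplan-Meier estimate; degenerate
(tied) predictions collapse bins, which are reported with missing
values rather than dropped. The Kaplan-Meier machinery itself wraps
lifelines.

## Synthetic data

The generator emulates a two-block cohort: iid standard-Gaussian
covariates, per-subject `(mu_i, y0_i)` through the model's own links,
inverse-Gaussian hitting times, independent exponential censoring
(optionally truncated administratively). The reference design — n=200,
`mu = -1 - 0.1 c1 + 0.1 c2`, `log y0 = 2 + 0.1 g1 + 0.2 g2`,
Exp(0.1) censoring — censors roughly half the cohort (Monte-Carlo
fraction ~51%, standard error 0.1 pp at 200k subjects) and is the
default scenario for tests and examples.

Sampling uses the shape/mean parameterization: for `mu < 0`,
`IG(mean = y0/|mu|, shape = y0^2)` via scipy's transformation sampler;
for `mu = 0` the closed form `y0^2 / chi^2_1`; for `mu > 0` an escape
indicator with probability `1 - exp(-2 y0 mu)`, otherwise a draw from
the mirrored-drift law `FHT(y0, -mu)` (the conditional law given a
finite hit). Correctness is established distributionally: moment
checks, Kolmogorov-Smirnov against the model CDF, and a
probability-integral transform across heterogeneous subjects.

What the generator does **not** emulate: correlated or non-Gaussian
covariates, informative or covariate-dependent censoring, measurement
error, and block correlation structure typical of expression data.
Passing tests therefore demonstrate correctness of the fitting and
evaluation machinery under the stated design, not robustness of the
model on real cohorts.

## Problem sizes and defaults used in the checks

The package's own verification runs at desk scale, chosen to exercise
each claim fully: distribution-layer identities on randomized points;
gradient checks on 1000 subjects; convergence-to-MLE on the n=200
reference realization with 10^4 cyclical iterations against an
independent BFGS optimum; parameter recovery at n=5000 uncensored with
3000 iterations; intrinsic variable selection at p=1000 per parameter,
n=100, with 10-fold CV over 200 non-cyclical iterations; censoring
fraction by 2-4 x 10^5 Monte-Carlo subjects. The two boosting variants
are compared at (m, m) vs 2m with m = 3000, where both have converged.

## Known limitations

* Linear base learners only; no trees or splines, and no per-dimension
  learner heterogeneity.
* Only Wiener-process hitting times; Gamma/Poisson/Beta-process FHT
  variants and time-dependent boundaries are out of scope.
* The cyclical 2-D tuning is more expensive than the non-cyclical 1-D
  search by roughly the grid size; prefer the non-cyclical variant when
  `p` is large.
* The likelihood surface can be non-smooth for near-degenerate censored
  configurations; fits then abort with a `NumericalFailure` rather than
  returning partial estimates, and the retry helper is the intended
  recovery path.
* No rule is offered for assigning clinical vs molecular blocks to the
  drift or the level: that is a subject-matter decision to make before
  fitting, and both assignments are cheap to compare.
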