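"""Integrating a clinical block and a molecular block in one model.

The two-parameter structure gives a natural data-integration scheme:
let one parameter depend on the low-dimensional clinical covariates and
the other on the high-dimensional molecular ones — no weighting schemes,
and no covariate can act on both parameters with contradictory signs.
Which block drives which parameter is a modelling choice to make in
advance; this script fits both assignments and compares their held-out
Integrated Brier Score.
"""

import numpy as np
import pandas as pd

import fhtboost as fb

# synthetic cohort: 3 clinical covariates act on the drift,
# 40 "genes" (5 informative) act on the initial health level
rng_seed = 17
p_genes = 40
beta = np.zeros(4)
beta[:4] = [-1.0, -0.3, 0.2, 0.15]
gamma = np.zeros(p_genes + 1)
gamma[0] = 2.0
gamma[1:6] = [0.25, -0.25, 0.2, -0.2, 0.15]
design = fb.SimulationDesign(n=300, beta=beta, gamma=gamma,
                             censoring_rate=0.08, seed=rng_seed,
                             mu_prefix="clin", y0_prefix="gene")
data, designs, _ = fb.simulate_dataset(design)

clinical = pd.DataFrame(designs.X_mu, columns=designs.mu_names)
molecular = pd.DataFrame(designs.X_y0, columns=designs.y0_names)
tr, te = fb.train_test_split(data.n, seed=rng_seed, test_fraction=1 / 3)

for label, pair in [
        ("clinical -> drift, genes -> level",
         fb.DesignPair(clinical, molecular)),
        ("genes -> drift, clinical -> level",
         fb.DesignPair(molecular, clinical))]:
    result = fb.cv_select(
        data.subset(tr), pair.subset(tr),
        fb.BoostingConfig(variant="noncyclical"),
        fb.CVPlan(K=5, max_mstop=150, seed=rng_seed))
    model = result.model
    test = data.subset(te)
    times = np.unique(test.time)[:-1]
    S = model.predict_survival(
        pd.DataFrame(pair.subset(te).X_mu, columns=pair.mu_names),
        pd.DataFrame(pair.subset(te).X_y0, columns=pair.y0_names),
        times=times).to_numpy()
    G = fb.km_estimator(data.subset(tr), "censoring")
    curve = fb.brier_curve(times, S, test, G)
    ibs = fb.integrated_brier_score(curve["time"], curve["brier"])
    n_sel = (np.count_nonzero(model.state.beta[1:]) +
             np.count_nonzero(model.state.gamma[1:]))
    print(f"{label}: cv mstop={result.chosen[0]:3d}, "
          f"{n_sel:2d} covariates selected, test IBS={ibs:.4f}")

print("\nLower IBS = better predictions. The assignment matching the "
      "data-generating\nmechanism (clinical->drift here) should win; with "
      "real data the choice is the\nanalyst's, made before fitting.")
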