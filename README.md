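# funsurf — dynamic survival prediction from longitudinal laboratory markers

After curative resection of colorectal liver metastases, routinely collected
laboratory markers (CEA, CA19-9, GGT, RDW-SD, RDW-CV, and the composite
indices APRI, FIB-4, S-index, NLR) keep arriving at every follow-up visit.
Static prognostic models throw that stream away; `funsurf` implements a
*functional survival forest* that uses it:

1. **Multivariate functional PCA (MFPCA).** Each marker's sparse, irregular,
   noisy measurements on the 12-month postoperative window are modelled as a
   latent smooth process X_j(t) observed with error. A PACE-type estimator
   smooths the pooled mean μ̂_j(t) and the off-diagonal raw covariances
   Ĉ_j(s,t), eigendecomposes under trapezoid quadrature, and recovers subject
   scores ξ̂_ij as best linear unbiased predictors given each subject's own
   visits. Stacking the univariate scores across the 9 markers and
   eigendecomposing their sample covariance gives multivariate components;
   the retained count is the smallest explaining ≥ 97% of total variance.
2. **Random survival forest (RSF).** The MFPC scores ρ̂_i enter a random
   survival forest (log-rank splits, Nelson–Aalen/Kaplan–Meier terminal
   estimates) alongside 18 clinicopathologic covariates. Three nested
   variants are compared: **A** covariates only, **B** + preoperative marker
   values, **C** + longitudinal MFPC scores.
3. **Dynamic prediction by landmarking.** At a landmark s the subject's
   scores are re-estimated from measurements observed up to s only and the
   conditional event-free probability Ŝ(t|s) = Ŝ(t)/Ŝ(s) is updated — the
   prognosis sharpens visit by visit.
4. **Evaluation.** Time-dependent AUC (cumulative cases / dynamic controls)
   and Brier score, both with inverse-probability-of-censoring weights, under
   repeated stratified 5-fold cross-validation with the whole feature
   pipeline refit inside every training fold; external validation with
   bootstrap CIs; quantile calibration tables.

Because no patient-level cohort is distributed, the package ships a
first-class synthetic-cohort generator with full ground truth: latent
multivariate trajectories from shared orthonormal components, Poisson visit
schedules, Weibull proportional hazards driven by baseline covariates (γ) and
latent scores (α), linked progression/death times, and administrative
censoring. Every statistical claim in the test suite is checked against that
ground truth or against independent oracles.

## Worked example

```python
import numpy as np
from funsurf import FunctionalSurvivalForest, SimulationConfig, simulate_cohort

cohort, truth = simulate_cohort(SimulationConfig(n_subjects=300, seed=7))
model = FunctionalSurvivalForest(variant="C", outcome="pfs",
                                 n_trees=300, random_state=0).fit(cohort)
print(f"components retained (97% rule): {model.mfpca_.n_components_}")
print(f"out-of-bag concordance:         {model.forest_.oob_cindex_:.3f}")

subject = cohort.subjects[0]
for s in (0.0, 6.0, 12.0):
    pred = model.predict_conditional(subject, landmark=s)
    p36 = pred.survival[np.argmin(np.abs(pred.times - 36.0))]
    print(f"landmark {s:4.1f} m: P(event-free at 36 m) = {p36:.3f}")
```

prints

```
components retained (97% rule): 12
out-of-bag concordance:         0.673
landmark  0.0 m: P(event-free at 36 m) = 0.341
landmark  6.0 m: P(event-free at 36 m) = 0.409
landmark 12.0 m: P(event-free at 36 m) = 0.618
```

Twelve multivariate components carry 97% of the stacked-score variance; the
forest discriminates progression risk out-of-bag at C ≈ 0.67; and for this
subject the predicted 36-month event-free probability rises from 0.34 at
surgery to 0.62 once twelve months of favourable marker trajectories have
been observed — the landmark update in action (both surviving to s and the
new marker information contribute to the rise).

A command-line interface wraps the same pipeline:

```bash
funsurf simulate --n-subjects 300 --seed 1 --out sim/       # cohort CSVs + truth.json
funsurf fit --config run.yaml                               # CV + VIMP + artifacts
funsurf predict --longitudinal sim/longitudinal.csv --baseline sim/baseline.csv \
    --outcomes sim/outcomes.csv --subject S0001 --landmarks 0,3,6,9,12 \
    --seed 0 --out curves.csv
funsurf study --seed 0                                      # property-check report
```

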