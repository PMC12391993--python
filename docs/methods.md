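# Methods

## Model

Observed values of marker j for subject i are modelled as noisy evaluations of
a latent smooth process on the postoperative window T = [0, 12] months:

    y_ij(t) = X_ij(t) + ε,   X_ij(t) = μ_j(t) + Σ_k ξ_ijk φ_jk(t),
    ε ~ N(0, σ_j²),

with the preoperative draw (taken within one week before surgery) mapped to
t = 0. The ξ_ijk are the univariate functional principal component scores;
stacking them across the 9 markers and eigendecomposing their sample
covariance (1/(n−1) normalization) yields multivariate components c_m with
eigenvalues ν_m and subject scores ρ̂_im = ξ̂_iᵀ c_m. The multivariate
combination operates on estimated univariate scores — the score-space
construction of multivariate FPCA — which is tractable for nine markers and
identical in population to the joint-covariance construction when the
univariate bases are rich enough. The hazard model is fully nonparametric: a
random survival forest on (clinicopathologic covariates, ρ̂_i), with
conditional survival at landmark s obtained as Ŝ(t)/Ŝ(s) after re-estimating
scores from data observed up to s.

### Estimation steps and numerical choices

* **Grid and quadrature.** 51 equispaced points on [0, 12]; trapezoid weights
  throughout. The eigenproblem is solved on W^{1/2} Ĉ W^{1/2} (symmetric), so
  returned eigenfunctions are orthonormal under the grid quadrature to
  machine precision; negative eigenvalues are clipped to zero (PSD repair).
  Signs are fixed by making each eigenfunction's entry of maximal magnitude
  positive.
* **Pre-transforms.** Right-skewed markers (CEA, CA19-9, GGT, APRI, FIB-4,
  S-index, NLR) receive log1p then z-standardization; RDW-SD/RDW-CV and any
  unrecognized marker name receive z-standardization only. Transform
  parameters are estimated on the fitting data and stored with the fit.
  Marker scales differ by orders of magnitude and the multivariate step is
  scale-sensitive, hence standardization is not optional.
* **Mean smoothing.** Pooled observations are binned onto grid cells (the bin
  abscissa is the within-bin mean time, which keeps data lying on a line
  exactly linear); a cubic smoothing spline with GCV-selected penalty
  (overridable via `mean_lambda`) is fitted to the binned means with bin
  counts as weights.
* **Covariance smoothing.** Off-diagonal raw cross-products are binned onto
  the grid lattice and smoothed by a local-linear estimator with separable
  Gaussian kernel, default bandwidth 1.5 months; the per-target 3×3 normal
  equations are solved in one batched call. The measurement-error variance is
  the average positive gap between the smoothed raw variance and the surface
  diagonal over the central half of the window, floored at 0. `bandwidth=0`
  switches to the raw binned covariance (including same-time products), valid
  only for noiseless dense common-grid designs; it makes the estimator agree
  exactly with weighted matrix PCA, which the tests exploit.
  The fixed default bandwidth attenuates eigenvalues of high-curvature
  components (≈ 0.7× per axis for a full-period oscillation on the window);
  correlation-based quantities (score recovery, discrimination) are
  unaffected, but absolute eigenvalues of fast-varying components are
  conservative.
* **Scores.** Conditional-expectation (BLUP) scores
  ξ̂ = Λ Φᵀ (Φ Λ Φᵀ + σ² I)⁻¹ (y − μ̂) at each subject's own times
  (eigenfunctions linearly interpolated from the grid); a jitter of
  1e-10·(1+λ₁) keeps the system solvable in the noiseless dense limit.
  Subjects with no usable observation receive prior-mean (zero) scores and a
  sparse-information flag.
* **Component retention.** Per marker: cumulative PVE ≥ 0.99, capped at 5
  components. Multivariate: smallest m with cumulative PVE ≥ 0.97
  (inclusive), overridable by a fixed count. Both thresholds are refit inside
  every cross-validation training fold; held-out subjects are only projected.

### Survival forest

Backed by scikit-survival's RandomSurvivalForest: log-rank splitting,
Nelson–Aalen cumulative hazards and Kaplan–Meier survival curves at the
leaves, bootstrap resampling with out-of-bag concordance. Defaults: 1000
trees, mtry = √p, minimum terminal node size 15 *samples* (the backing engine
exposes sample counts, not event counts), no depth cap. Missing covariates
are imputed by training-set median (continuous) or mode (categorical); unseen
categorical levels at prediction time encode to all-zero indicator rows with
a warning. Variable importance is the mean increase in concordance error
after jointly permuting a feature or feature group over seeded permutations;
a feature the forest never split on gets exactly zero. Importance is computed
on whatever data the caller supplies (training data approximates the
out-of-bag variant; a held-out fold gives honest importance).

### Dynamic prediction

One forest trained on full-window (12-month) scores serves every landmark;
landmark honesty lives entirely in the score projection, which truncates each
subject's measurements at s (baseline t = 0 included). Conditional curves are
Ŝ(t)/Ŝ(s) on a horizon grid to 60 months, clipped to [0,1], with Ŝ(s|s) = 1
pinned exactly; a division floor of 1e-6 on Ŝ(s) raises an explicit error
rather than dividing silently. A natural-cubic-spline smoothed and
isotonically re-monotonized copy is attached for display only; every metric
uses the raw values.

### Evaluation

* **Censoring weights.** Kaplan–Meier of the censoring distribution Ĝ
  (standard risk-set convention). Events by the horizon weigh 1/Ĝ(T⁻),
  subjects at risk at the horizon 1/Ĝ(t), others 0. For cross-validation Ĝ is
  estimated on the training fold; for external validation on the external
  cohort itself.
* **AUC** is the IPCW cumulative-cases/dynamic-controls estimator (Uno type);
  tied risk scores count 1/2. **Brier** is the Graf-style IPCW mean squared
  error. Both are cross-checked in the tests against scikit-survival's
  independent implementations and against brute-force pairwise enumeration.
* **Horizons.** 12 and 36 months by default, plus 13 months for the early
  recurrence endpoint (progression within 13 months). The 60-month horizon of
  the prediction window is not evaluated by default because administrative
  censoring is uniform to 60 months, so Ĝ(60⁻) ≈ 0 and IPCW weights diverge.
* **Cross-validation.** Stratified by the event indicator, k = 5, repeats
  configurable (10 by default in the pipeline); metrics are averaged over
  folds and repeats. Fold models can be fingerprinted (SHA-256 of the pickled
  forest) to audit that held-out data never touches a training fit.
* **External validation** reports subject-level bootstrap percentile 95% CIs;
  with a single bootstrap replicate the CI degenerates to missing and only
  the point estimate is reported.
* **Calibration** bins predicted event probabilities into quantile groups and
  compares each group's mean prediction with the Kaplan–Meier observed event
  probability and its Greenwood CI; constant predictions collapse to a single
  bin.

## Synthetic cohort generator

The generator realizes exactly the latent-process assumption the analysis
makes, with full ground truth for tests.

* **Components.** Orthonormal basis on [0, 12]: φ₁ = level (constant),
  φ_k = √(2/T)·sin(2(k−1)πt/T) for k ≥ 2. The shape components vanish at
  t = 0 by construction, so their scores are invisible in the preoperative
  value — the regime in which longitudinal modelling can add information
  beyond baseline markers. Default eigenvalues (6, 3, 1.5); fixed seeded
  loading matrix so all markers share all components; marker means follow a
  post-surgery transient b₀ + b₁·exp(−t/2).
* **Visits.** {0} ∪ Poisson-process times in (0, 12], expected count 5/year
  (emulating a schedule of roughly six assessments in the first year with
  occasional missed draws), resampled to guarantee the ≥ 2 postoperative
  measurements that eligibility requires.
* **Outcomes.** Progression hazard λ₀(t)·exp(γᵀx + αᵀρ) with Weibull baseline
  (shape 1.2, scale 28 months — median progression-free time near 17 months
  before censoring); death = progression + exponential gap (mean 18 months);
  administrative censoring uniform on [6, 60] months. Defaults yield ≈ 60%
  progression events and ≈ 30% deaths. Default α = (0.25, 0.35, 0.30) puts
  real signal on trajectory shape; γ is nonzero for a handful of established
  prognostic covariates (bilobar disease, metastasis count and size,
  extrahepatic disease, R0 resection, nodal stage). Covariates are centred
  inside the hazard so the marginal event fraction tracks the Weibull
  baseline.
* **Baseline covariates.** 18 clinicopathologic variables with marginals
  loosely matching a resected colorectal-liver-metastasis cohort (age ~
  N(59, 10²), 63% male, 44% bilobar, median 2–3 metastases, ...).
* **What it does not emulate.** Exact marginal distributions of real marker
  panels (markers are generated on the latent Gaussian scale under neutral
  names, so the name-keyed log1p rules do not fire; an optional
  exponentiation produces skewed positive values), multi-hospital batch
  effects, informative visit schedules, and measurement error that varies
  with disease state. Passing tests therefore demonstrate correctness of the
  estimators under the model's own assumptions, not performance on real
  patients.

## Design choices where the design was open

* Composite markers with a missing constituent are *absent* at that visit,
  never imputed — sparse FPCA tolerates missingness and provenance stays
  auditable. Duplicate (subject, marker, time) records are rejected, not
  averaged.
* Albumin enters the S-index in g/L: with platelets ≈ 200×10⁹/L and ALB ≈ 40
  g/L the index sits near 0.1, the plausible clinical magnitude; g/dL would
  shift it by two orders. The AST upper limit of normal defaults to 40 U/L
  and is an explicit, logged argument.
* The 97% rule is applied to the variance of stacked univariate scores (the
  score-space convention), not to raw-curve variance; the threshold is
  exposed.
* Landmark projections use all data up to s including the baseline draw.
* Scores at a landmark come from a single full-window model; landmark-specific
  forests would be a valid alternative at substantially higher cost and are
  not implemented.
* CV metrics are averaged over folds (pooling out-of-fold predictions is the
  natural alternative; fold averaging keeps per-fold censoring estimation
  honest).
* No multiple-testing adjustment: the package reports estimates and CIs, not
  hypothesis tests.

## Problem sizes in tests and the acceptance script

Component-recovery checks run at n = 400 subjects; the selection-rule check
at 20 replicates of n = 150 with 6 markers; forest sanity at n = 500; the
model-C-vs-B comparison at 10 replicates of n = 300 with 6 markers, 5-fold
CV, 150 trees; consistency of dynamic predictions contrasts n = 400 against
n = 1600 with dense (10/year) visits so that score noise does not mask the
ensemble's convergence. These sizes give stable Monte-Carlo margins for the
properties being asserted while keeping a full run to a few minutes on one
CPU.

## Known limitations

* Univariate eigenvalues of fast-oscillating components are attenuated by the
  fixed covariance bandwidth (see above); bandwidth selection by
  cross-validation is not implemented.
* The BLUP scores assume Gaussian latent processes and errors; heavy-tailed
  marker noise will leak into the scores despite the log1p pre-transforms.
* OOB-based permutation importance is approximated by permutation importance
  on supplied data (the backing engine does not expose per-tree OOB
  predictions).
* The minimum terminal node size counts samples, not events.
* IPCW metrics become unstable within a few months of the maximal censoring
  time; horizons are capped accordingly.
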