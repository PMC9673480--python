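# Methods

## 1. Statistical model

### 1.1 Mixed models

Every regression carries a mother-level (dyad) random intercept:

```
y_ij = x_ij' β + u_i + ε_ij,   u_i ~ N(0, σ_u²),  ε_ij ~ N(0, σ²)
```

for dyad i at visit j. Models are fit by REML with statsmodels MixedLM;
fixed-effect inference uses Wald z statistics on the estimated
fixed-effect covariance. Two degenerate regimes are handled explicitly:

- one observation per subject → the random intercept is unidentifiable
  and the model is fit by OLS (σ_u² = 0);
- the REML solution on the zero-variance boundary can return an invalid
  Hessian-based covariance (negative diagonal); at that boundary the
  model *is* OLS, so the engine falls back to the OLS fit.

The compound-symmetry (random-intercept) covariance is a simplification
of an unstructured longitudinal covariance over visits; it targets the
same fixed-effect mean structure, at some cost in small-sample efficiency
when visit variances differ strongly.

### 1.2 Counterfactual mediation

For exposure X, mediator M, outcome Y, covariates Z:

1. `Y ~ X + Z` → total effect c₁
2. `M ~ X + Z` → a₁
3. `Y ~ X + M (+ X:M) + Z` → b₁ (and b₃ when the interaction is kept)

Per exposure level x:

- indirect(x) = a₁ (b₁ + b₃ x)
- direct(x) = c₁ − indirect(x)
- proportion mediated = 100 · indirect(x) / c₁

These linear closed forms coincide with the counterfactual
natural-indirect/natural-direct effects for linear models. All three
steps are fit on **one shared complete-case set** (rows complete in every
variable used by any step) so the decomposition identity
`direct + indirect = c₁` holds exactly; the total-effect model is
additionally reported on its own, usually larger, complete-case set
(`n_total_effect`) because mediator missingness (infant blood drawn at
only one of V3/V4 per infant) otherwise silently shrinks the total-effect
sample.

Interaction screening: the X:M Wald test at α = 0.05 in the step-3 model.
On a significant screen a continuous adiposity exposure is dichotomised —
BMI ≥ 25 kg/m² (closed bound) "overweight", FMI > 9 (open bound, 9.0 is
normal) "excessive" — the interaction is retained, and effects are
reported at both levels.

### 1.3 Monte Carlo confidence interval

Sampling uncertainty of the product a₁(b₁ + b₃x) is assessed by the Monte
Carlo method for mediation: draw a₁* ~ N(â₁, V̂(â₁)) and
(b₁*, b₃*) ~ MVN((b̂₁, b̂₃), V̂) jointly from the outcome model —
independently of a₁*, since the mediator and outcome models are fit
separately and share no estimated parameters — and form
a₁*(b₁* + b₃*x) per draw. The 95% CI is the percentile interval over
20,000 draws (default; minimum 1,000); a two-sided Monte Carlo p-value
against zero is reported alongside. The covariance factor uses an
eigendecomposition with explicit symmetry and positive-semidefiniteness
checks.

Back-transforms for log-scale outcomes: a coefficient β maps to a percent
difference `100(e^β − 1)`; for a log-scale *exposure*, a p% increase
shifts the outcome by `β ln(1 + p/100)`.

## 2. Synthetic cohort generator

### 2.1 Design

Each dyad has maternal anthropometry (BMI ~ N(23.6, 3²) with a small
postpartum drift; FMI linearly coupled to BMI plus noise), an infant sex,
and visits V1 (≤ 72 h), V2 (1–3.5 mo), V3 (3.5–6 mo), V4 (6–8.5 mo).
Hormones are log-normal with visit-specific medians chosen to mimic
published breast-milk and plasma ranges (e.g. milk leptin medians
419/90/48/33 pg/mL across V1–V4; milk insulin falls steeply after
colostrum; adiponectin is comparatively stable). The mediation structure
is planted on the configured hormone (default leptin):

```
log M = log(med_visit) + a₁ (BMI − 23.6) + u_i + ε
log Y = log(med_visit) + c₁′ (BMI − 23.6) + (b₁ + b₃(BMI − 23.6)) Mc + v_i + ε′
```

where Mc is the structural deviation of the mediator from its expected
visit median, and u, v are dyad random intercepts. Fitting with a visit
covariate absorbs the visit medians, so a₁/b₁/b₃/c₁′ are recoverable by
the engine. An analogous `InfantEffects` block plants the RQ2 pathway
log milk → log infant plasma → infant weight.

Realism features: assay LOD censoring (insulin 12 pg/mL, leptin
11 pg/mL, adiponectin 5 ng/mL) blanks the value and raises a `*_blod`
flag; infant blood is drawn from everyone at V2 but from each infant at
only one of V3/V4 (50/50 split); per-visit retention defaults to
{V1: 0.65, V2: 1.0, V3: 0.94, V4: 0.91}; 24-h test-weighing logs are
generated per visit with feed volumes that sum exactly to the drawn daily
total, with optional missing-weight and > 400 g spike perturbations.
`CohortTruth` retains every parameter, random intercept and uncensored
latent value, and round-trips through JSON.

### 2.2 Generator settings used for engine validation

Recovery and coverage claims are about the *estimator*, so validation
scenarios generate with `lod_censor=False` and dropout zeroed: half-LOD
substitution is a known, deliberate bias source in the data model (it
attenuates slopes when a hormone has substantial below-LOD mass), and
mixing it into engine validation would conflate data-model bias with
estimator error.

## 3. Preprocessing and test weighing

- Non-detectable assays are substituted at LOD/2, flagged, idempotently.
  Frame-level substitution acts only on `*_blod`-flagged entries — a
  censored assay reports "non-detectable", not a numeric value.
- Indices: BMI = weight/height², FMI/FFMI analogously from fat and
  fat-free mass. Milk energy by Atwater factors 9/4/4 kcal/g
  (fat/protein/carbohydrate).
- Age is centred per visit (age − mean age at that visit), so visit terms
  capture between-visit change and `centered_age` captures within-window
  timing.
- Feed volume = post − pre weight in grams, read as mL (density
  1 g/mL). Negative differences and spikes > 400 g become missing; spikes
  are converted **before** the > 3-missing discard rule. Hot-deck
  imputation fills a missing feed from the nearest observed feed by
  position, preferring the preceding one on ties — deterministic by
  construction.

## 4. Validation and problem sizes

The package's own validation choices (also run by
`scripts/acceptance.py` and `tests/test_acceptance.py`):

- **Worked-example arithmetic** on published-scale coefficients
  (proportion mediated, direct share, per-10%-increase effects,
  log-scale back-transforms).
- **Oracle equivalence.** `monte_carlo_ci` endpoints at 10⁶ draws agree
  within 0.005 with quantiles of the exact product-of-independent-normals
  distribution computed by numerical integration (observed deviation
  ≈ 1×10⁻⁴). `fit_lmm` agrees with an explicit GLS solve at the fitted
  variance components within 1e-4 relative on 20-subject toys.
- **Parameter recovery.** 200 replicates at n = 400 dyads, 3
  post-colostrum visits, a₁ = 0.5, b₁ = 0.8, b₃ = 0, c₁′ = 0.2: mean
  indirect within 0.02 of 0.40, mean direct within 0.02 of 0.20.
- **CI coverage.** A 1,000-replicate study at n = 200 gave 95.7% coverage
  of the true indirect effect by the 95% Monte Carlo CI (mean estimate
  0.3997, empirical SD 0.026). The shipped tests rerun this at 400
  replicates (binomial SE ≈ 1.1%) against the 95% ± 2% band, and check
  that under b₁ = b₃ = 0 the CI covers zero in ≥ 93% of 150 replicates.
- **Determinism and conservation.** Identical parameters + seed give
  byte-identical cohorts and mediation JSON; clean synthetic feed logs
  conserve the generated daily total exactly; QC reproduces the spike and
  missing-feed rules on constructed fixtures.

Typical runtimes (one CPU): a MixedLM fit on ~600 rows ≈ 0.2 s; one full
mediation replicate ≈ 0.9 s at n = 200 and ≈ 1.9 s at n = 400; the
acceptance script ≈ 15 minutes, dominated by the replicate studies.

## 5. Limitations

- Compound-symmetry covariance instead of unstructured longitudinal
  covariance (§1.1).
- Mediator and outcome draws are independent; if both models were fit
  jointly their estimates would correlate, which the MC interval ignores
  (standard for separately fitted models).
- No sensitivity analysis for unmeasured mediator–outcome confounding,
  no multiple-mediator models, no bootstrap/quasi-Bayesian alternatives.
- The mediation grids report unadjusted p-values; the number of tests in
  each grid is emitted so users can apply their own correction.
- Half-LOD substitution biases slopes toward zero for hormones with
  substantial below-LOD mass (notably late-lactation milk leptin); a
  censored-likelihood model is out of scope.
- RQ2 uses concurrent-visit milk-hormone exposure (not lagged).
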