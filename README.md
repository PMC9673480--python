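# milktriad

Counterfactual mediation analysis of the mother–milk–infant triad:
does maternal adiposity shape the appetite-regulating hormones (leptin,
insulin, adiponectin) in human milk *through* the mother's circulating
hormone levels, and do milk hormones shape infant intake and growth
*through* the infant's circulating levels?

The package provides, end to end:

- **Synthetic cohort generator** (`milktriad.synthetic`) — longitudinal
  mother–infant dyads over four visits (V1 ≈ 2 days to V4 ≈ 7 months) with
  realistic log-normal hormone marginals, assay limit-of-detection
  censoring, staggered infant blood sampling, visit dropout and 24-h
  test-weighing feed logs, plus a `CohortTruth` record of every structural
  parameter for validation.
- **Preprocessing** (`milktriad.preprocess`) — half-LOD substitution for
  non-detectable assays, BMI/FMI/FFMI computation, adiposity groups
  (BMI ≥ 25 overweight; FMI > 9 excessive), milk energy by Atwater
  factors, per-visit age centring and visit-window assignment.
- **Test weighing** (`milktriad.weighing`) — feed volumes from pre/post
  weights, QC (spikes > 400 g and negative differences become missing;
  logs with > 3 missing feeds are discarded), deterministic hot-deck
  imputation and 24-h intake summaries.
- **Mixed-model engine** (`milktriad.lmm`) — fixed effects plus a
  mother-level random intercept (statsmodels MixedLM, REML; OLS in
  degenerate designs), Wald tests, interaction screening and log-scale
  back-transforms.
- **Mediation engine** (`milktriad.mediate`) — the four-step
  counterfactual decomposition with a Monte Carlo confidence interval for
  the product-of-coefficients indirect effect.
- **Study pipeline and CLI** (`milktriad.pipeline`, `milktriad`
  command) — the full RQ1/RQ2 analysis grids, simulation studies, JSON +
  markdown reports, all seeded and hash-stable.

## The method in brief

For exposure X (maternal adiposity), mediator M (maternal plasma hormone)
and outcome Y (log milk hormone), three mixed models are fit on one shared
complete-case set:

1. `Y ~ X + covariates` → total effect **c₁**
2. `M ~ X + covariates` → path **a₁**
3. `Y ~ X + M (+ X:M) + covariates` → paths **b₁**, **b₃**

The indirect effect at exposure level x is `a₁·(b₁ + b₃·x)`, the direct
effect is `c₁ − indirect`, and the proportion mediated is
`100·indirect/c₁`. Uncertainty comes from the Monte Carlo method for
assessing mediation: draw `a₁*` from its estimated normal sampling
distribution and `(b₁*, b₃*)` jointly from the outcome-model multivariate
normal (independently, as the models share no parameters), form the
product per draw, and take percentile quantiles. When the exposure–mediator
interaction screen is significant, the continuous exposure is dichotomised
at the conventional adiposity cut and effects are reported per level.

## Worked example

```python
from milktriad import CohortParams, generate_cohort, preprocess_visit_table
from milktriad.mediate import MediationSpec, run_mediation

params = CohortParams(
    n_dyads=300, seed=42, a1=0.5, b1=0.8, c1_prime=0.2, lod_censor=False,
    dropout={"V1": 0.0, "V2": 1.0, "V3": 1.0, "V4": 1.0},
)
visits, feed_logs, truth = generate_cohort(params)
table = preprocess_visit_table(visits)

spec = MediationSpec(
    exposure="maternal_bmi",
    mediator="log_plasma_leptin",
    outcome="log_milk_leptin",
    covariates=("C(visit)",),
    seed=7,
)
res = run_mediation(table, spec)
eff = res.levels["overall"]
print(f"total effect  c1 = {res.c1:.3f}")
print(f"paths         a1 = {res.a1:.3f}, b1 = {res.b1:.3f}")
print(f"indirect = {eff.indirect:.3f}  95% CI [{eff.mc_ci[0]:.3f}, {eff.mc_ci[1]:.3f}]")
print(f"direct   = {eff.direct:.3f}")
print(f"proportion mediated = {eff.proportion_mediated:.0f}%")
```

Output (the generating truth is a₁ = 0.5, b₁ = 0.8, c₁′ = 0.2, so the true
indirect effect is 0.40 and the true direct effect 0.20):

```
total effect  c1 = 0.589
paths         a1 = 0.495, b1 = 0.765
indirect = 0.378  95% CI [0.336, 0.421]
direct   = 0.210
proportion mediated = 64%
```

## Command line

```bash
milktriad simulate --seed 42 --n-dyads 223 --a1 0.5 --b1 0.8 --out cohort
milktriad preprocess --visits cohort/visits.csv --out visits_pre.csv
milktriad intake --feed-logs cohort/feed_logs.csv --out intake.csv
milktriad rq1 --visits cohort/visits.csv --feed-logs cohort/feed_logs.csv --seed 42 --out results
milktriad rq2 --visits cohort/visits.csv --feed-logs cohort/feed_logs.csv --seed 42 --out results
milktriad simstudy --seed 1 --n-reps 100 --n-dyads 200 --out simstudy.csv
milktriad report --results results/mediation_results.json --out report.md
```

`rq1` iterates {BMI, FMI} × {leptin, insulin, adiponectin} with maternal
plasma mediators; `rq2` iterates the three milk hormones against intake
(total and per-feed) and growth (weight, length, FMI, body-fat %) with
infant plasma mediators, reporting both the full-sample total-effect n and
the reduced mediation n. Identical config + seed reproduce byte-identical
outputs.

## Validation

`scripts/acceptance.py --seed 1 --out results/acceptance.json` recomputes
the headline quantities from scratch: worked-example arithmetic,
Monte Carlo CI endpoints against an integrated product-distribution
oracle, mixed-model agreement with an explicit GLS solve, parameter
recovery and 95% CI coverage on simulated cohorts, and feed-log volume
conservation. The same guarantees run as `tests/test_acceptance.py` in
the pytest suite (`python -m pytest -q tests/`). See `docs/methods.md`
for the model details, generator design and limitations.
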