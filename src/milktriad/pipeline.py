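"""End-to-end orchestration of the two research questions and simulations.

RQ1 asks whether associations between maternal body composition (BMI, FMI)
and milk hormone concentrations (leptin, insulin, adiponectin) are mediated
through the mother's circulating concentration of the same hormone. RQ2
asks whether associations between milk hormones and infant outcomes (24-h
milk intake, intake per feed, weight, length, fat-mass index, body-fat %)
are mediated through the infant's circulating concentration. Both iterate
the mediation engine over an exposure x hormone (x outcome) grid with the
fixed covariate sets below, report unadjusted p-values together with the
number of tests run, and carry full provenance (formulas, n, seed) on every
emitted effect row.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .lmm import ModelSpec, fit_lmm, wald_p
from .mediate import MediationResult, MediationSpec, run_mediation, screen_and_dichotomize
from .preprocess import preprocess_visit_table
from .synthetic import CohortParams, generate_cohort
from .weighing import summarize_all

__all__ = [
    "RunConfig",
    "RQ1_COVARIATES",
    "RQ2_INTAKE_COVARIATES",
    "RQ2_GROWTH_COVARIATES",
    "prepare_analysis_table",
    "run_rq1",
    "run_rq2",
    "run_simulation_study",
    "results_to_markdown",
]

HORMONES = ("leptin", "insulin", "adiponectin")
RQ1_EXPOSURES = ("maternal_bmi", "maternal_fmi")
RQ1_COVARIATES = ("infant_sex", "C(visit)", "centered_age")
RQ2_INTAKE_OUTCOMES = ("total_24h_ml", "per_feed_ml")
RQ2_GROWTH_OUTCOMES = (
    "infant_weight_g", "infant_length_cm", "infant_fmi", "infant_bodyfat_pct",
)
RQ2_INTAKE_COVARIATES = (
    "milk_energy_kcal_l", "infant_sex", "infant_weight_g", "centered_age",
)
RQ2_GROWTH_COVARIATES = (
    "milk_energy_kcal_l", "total_24h_ml", "birth_weight_g", "infant_sex",
    "centered_age",
)


@dataclass
class RunConfig:
    """Configuration of a pipeline run.

    Either CSV input paths (visit table + feed logs) or synthetic cohort
    parameters; the seed drives both generation and Monte Carlo draws.
    """

    visit_csv: str | None = None
    feed_log_csv: str | None = None
    cohort: CohortParams | None = None
    n_draws: int = 20_000
    ci_level: float = 0.95
    seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        cohort = raw.pop("cohort", None)
        cfg = cls(**raw)
        if cohort is not None:
            cfg.cohort = CohortParams(**cohort)
        return cfg


def _child_seed(seed: int, *keys: int) -> int:
    """Deterministic sub-seed below 2**31."""
    return int(np.random.SeedSequence([seed, *keys]).generate_state(1)[0] % (2**31))


def prepare_analysis_table(config: RunConfig) -> pd.DataFrame:
    """Load or generate the cohort and produce the analysis-ready table.

    Applies preprocessing (LOD substitution, log columns, adiposity groups,
    centred age), computes intake summaries from the feed logs and merges
    them onto the visit rows. Dyads that never breastfed would be dropped
    at ingest; the synthetic generator emits breastfeeding dyads only.
    """
    if config.cohort is not None:
        params = config.cohort
        if params.seed is None:
            params = dataclasses.replace(params, seed=config.seed)
        visits, feed_logs, _ = generate_cohort(params)
    elif config.visit_csv is not None:
        visits = pd.read_csv(config.visit_csv)
        feed_logs = None
        if config.feed_log_csv is not None:
            from .weighing import feed_logs_from_frame

            feed_logs = feed_logs_from_frame(pd.read_csv(config.feed_log_csv))
    else:
        raise ValueError("config must provide either input CSVs or cohort parameters")

    table = preprocess_visit_table(visits)
    if feed_logs:
        weights = table[["dyad_id", "visit", "infant_weight_g"]].assign(
            infant_weight_kg=lambda d: d["infant_weight_g"] / 1000.0
        )
        intake = summarize_all(feed_logs, weights)
        intake = intake[intake["status"] == "ok"]
        table = table.merge(
            intake[["dyad_id", "visit", "total_24h_ml", "per_feed_ml", "per_kg_ml"]],
            on=["dyad_id", "visit"],
            how="left",
        )
    return table


def _require_columns(table: pd.DataFrame, cols: list[str], context: str) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"{context}: missing column(s) {missing}")


def run_rq1(
    table: pd.DataFrame,
    n_draws: int = 20_000,
    ci_level: float = 0.95,
    seed: int = 0,
) -> list[dict]:
    """Maternal adiposity -> maternal plasma hormone -> milk hormone.

    For each of BMI/FMI x leptin/insulin/adiponectin: screen the
    exposure-mediator interaction; on a significant screen the exposure is
    dichotomised at the adiposity cut and level-specific effects are
    reported. Colostrum (V1) rows are excluded — no maternal plasma exists
    there.
    """
    data = table[table["visit"] != "V1"].copy()
    results = []
    n_tests = len(RQ1_EXPOSURES) * len(HORMONES)
    for exposure in RQ1_EXPOSURES:
        for i, hormone in enumerate(HORMONES):
            mediator = f"log_plasma_{hormone}"
            outcome = f"log_milk_{hormone}"
            _require_columns(data, [exposure, mediator, outcome], f"RQ1 {hormone}")
            spec = MediationSpec(
                exposure=exposure,
                mediator=mediator,
                outcome=outcome,
                covariates=RQ1_COVARIATES,
                n_draws=n_draws,
                ci_level=ci_level,
                seed=_child_seed(seed, 1, RQ1_EXPOSURES.index(exposure), i),
            )
            spec, d, p_screen = screen_and_dichotomize(data, spec)
            res = run_mediation(d, spec)
            results.append(
                {
                    "rq": "RQ1",
                    "exposure": exposure,
                    "hormone": hormone,
                    "outcome": outcome,
                    "p_interaction_screen": p_screen,
                    "dichotomized": spec.exposure_mediator_interaction,
                    "n_tests_in_grid": n_tests,
                    "result": res,
                }
            )
    return results


def run_rq2(
    table: pd.DataFrame,
    n_draws: int = 20_000,
    ci_level: float = 0.95,
    seed: int = 0,
) -> list[dict]:
    """Milk hormone -> infant plasma hormone -> infant intake/growth.

    The total-effect model runs on its own (larger) complete-case set;
    mediation is restricted to rows with infant plasma, which only half the
    infants have at V3/V4, so the mediation n is reported alongside. When
    the exposure interacts with infant sex in the total-effect model,
    per-sex exposure estimates are emitted.
    """
    data = table[table["visit"] != "V1"].copy()
    data["sex_female"] = (data["infant_sex"] == "female").astype(float)
    results = []
    grid = [
        (o, RQ2_INTAKE_COVARIATES) for o in RQ2_INTAKE_OUTCOMES
    ] + [(o, RQ2_GROWTH_COVARIATES) for o in RQ2_GROWTH_OUTCOMES]
    n_tests = len(HORMONES) * len(grid)
    for hi, hormone in enumerate(HORMONES):
        exposure = f"log_milk_{hormone}"
        mediator = f"log_infant_plasma_{hormone}"
        for oi, (outcome, covariates) in enumerate(grid):
            _require_columns(data, [exposure, mediator, outcome], f"RQ2 {hormone}")
            if data[outcome].dropna().empty:
                raise ValueError(f"RQ2 outcome column {outcome!r} has no data")
            covs = tuple(c for c in covariates if c != outcome)
            # sex interaction in the total-effect model; the categorical sex
            # covariate is swapped for its 0/1 indicator so the interaction
            # term has a single interpretable coefficient
            sex_terms = tuple(
                "sex_female" if c == "infant_sex" else c for c in covs
            )
            sex_fit = fit_lmm(
                data,
                ModelSpec(
                    outcome=outcome,
                    fixed_terms=(exposure,) + sex_terms,
                    interactions=((exposure, "sex_female"),)
                    if "sex_female" in sex_terms
                    else (),
                ),
            )
            per_sex = None
            iname = f"{exposure}:sex_female"
            if iname in sex_fit.coef.index:
                p_sex = sex_fit.p_value(iname)
                if p_sex < 0.05:
                    b_m = float(sex_fit.coef[exposure])
                    b_int = float(sex_fit.coef[iname])
                    var_m = float(sex_fit.vcov.loc[exposure, exposure])
                    var_f = (
                        var_m
                        + float(sex_fit.vcov.loc[iname, iname])
                        + 2.0 * float(sex_fit.vcov.loc[exposure, iname])
                    )
                    per_sex = {
                        "p_sex_interaction": p_sex,
                        "male": {"beta": b_m, "p": wald_p(b_m, np.sqrt(var_m))},
                        "female": {
                            "beta": b_m + b_int,
                            "p": wald_p(b_m + b_int, np.sqrt(var_f)),
                        },
                    }
            spec = MediationSpec(
                exposure=exposure,
                mediator=mediator,
                outcome=outcome,
                covariates=covs,
                n_draws=n_draws,
                ci_level=ci_level,
                seed=_child_seed(seed, 2, hi, oi),
            )
            res = run_mediation(data, spec)
            results.append(
                {
                    "rq": "RQ2",
                    "exposure": exposure,
                    "hormone": hormone,
                    "outcome": outcome,
                    "per_sex": per_sex,
                    "n_tests_in_grid": n_tests,
                    "result": res,
                }
            )
    return results


def run_simulation_study(
    scenarios: list[dict],
    n_reps: int,
    seed: int = 0,
    n_draws: int = 5_000,
    covariates: tuple[str, ...] = ("C(visit)",),
) -> pd.DataFrame:
    """Bias / empirical SE / CI coverage of the mediation engine.

    Each scenario is a dict of CohortParams overrides (e.g. ``{"a1": 0.5,
    "b1": 0.8, "n_dyads": 400}``). Per replicate a fresh cohort is
    generated, preprocessed and mediated (maternal pathway, continuous BMI
    exposure, no interaction); the table reports, per scenario, the mean
    and SD of the indirect/direct estimates, the truth, coverage of the
    truth by the Monte Carlo CI and the fraction of CIs excluding zero.
    """
    rows = []
    for si, overrides in enumerate(scenarios):
        per_rep = simulate_mediation_replicates(
            overrides, n_reps, seed=_child_seed(seed, 3, si), n_draws=n_draws,
            covariates=covariates,
        )
        p = CohortParams(**{**overrides, "seed": 0})
        true_ind = p.a1 * p.b1
        true_dir = p.c1_prime
        rows.append(
            {
                "scenario": si,
                **{k: v for k, v in overrides.items()},
                "n_reps": n_reps,
                "true_indirect": true_ind,
                "true_direct": true_dir,
                "mean_indirect": per_rep["indirect"].mean(),
                "sd_indirect": per_rep["indirect"].std(ddof=1) if n_reps > 1 else np.nan,
                "mean_direct": per_rep["direct"].mean(),
                "bias_indirect": per_rep["indirect"].mean() - true_ind,
                "coverage_truth": per_rep["covers_truth"].mean(),
                "coverage_zero": per_rep["covers_zero"].mean(),
                "reject_zero": 1.0 - per_rep["covers_zero"].mean(),
                "n_eq_1": n_reps == 1,
            }
        )
    return pd.DataFrame(rows)


def simulate_mediation_replicates(
    overrides: dict,
    n_reps: int,
    seed: int = 0,
    n_draws: int = 5_000,
    covariates: tuple[str, ...] = ("C(visit)",),
) -> pd.DataFrame:
    """Per-replicate mediation estimates on freshly generated cohorts."""
    recs = []
    for rep in range(n_reps):
        params = CohortParams(**{**overrides, "seed": _child_seed(seed, rep)})
        visits, _, truth = generate_cohort(
            dataclasses.replace(params, dropout={"V1": 0.0, "V2": 1.0, "V3": 1.0, "V4": 1.0})
        )
        table = preprocess_visit_table(visits)
        spec = MediationSpec(
            exposure="maternal_bmi",
            mediator=f"log_plasma_{params.mediation_hormone}",
            outcome=f"log_milk_{params.mediation_hormone}",
            covariates=covariates,
            n_draws=n_draws,
            seed=_child_seed(seed, rep, 1),
        )
        res = run_mediation(table, spec)
        eff = res.levels["overall"]
        true_ind = truth.a1 * truth.b1
        recs.append(
            {
                "rep": rep,
                "a1": res.a1,
                "b1": res.b1,
                "c1": res.c1,
                "indirect": eff.indirect,
                "direct": eff.direct,
                "ci_lo": eff.mc_ci[0],
                "ci_hi": eff.mc_ci[1],
                "covers_truth": eff.mc_ci[0] <= true_ind <= eff.mc_ci[1],
                "covers_zero": eff.mc_ci[0] <= 0.0 <= eff.mc_ci[1],
            }
        )
    return pd.DataFrame(recs)


def results_to_markdown(results: list[dict]) -> str:
    """Human-readable per-level effect table mirroring the decomposition
    figure layout (indirect / direct / proportion mediated per level)."""
    lines = [
        "| RQ | exposure | hormone | outcome | level | indirect | 95% CI | direct | PM % | n |",
        "|----|----------|---------|---------|-------|----------|--------|--------|------|---|",
    ]
    for r in results:
        res: MediationResult = r["result"]
        for label, eff in res.levels.items():
            pm = "—" if eff.proportion_mediated is None else f"{eff.proportion_mediated:.0f}"
            lines.append(
                f"| {r['rq']} | {r['exposure']} | {r['hormone']} | {r['outcome']} "
                f"| {label} | {eff.indirect:.3g} "
                f"| [{eff.mc_ci[0]:.3g}, {eff.mc_ci[1]:.3g}] "
                f"| {eff.direct:.3g} | {pm} | {res.n_complete} |"
            )
    return "\n".join(lines) + "\n"


def write_results(results: list[dict], out_dir: str) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = []
    for r in results:
        d = {k: v for k, v in r.items() if k != "result"}
        d["result"] = json.loads(r["result"].to_json())
        payload.append(d)
    (out / "mediation_results.json").write_text(
        json.dumps(payload, indent=2), encoding="utf-8"
    )
    (out / "mediation_results.md").write_text(
        results_to_markdown(results), encoding="utf-8"
    )
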