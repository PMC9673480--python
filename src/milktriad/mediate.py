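"""Counterfactual mediation with product-of-coefficients inference.

The four-step procedure on longitudinal dyad data, all models carrying a
mother-level random intercept:

1. total effect:    outcome  ~ exposure + covariates            -> c1
2. mediator model:  mediator ~ exposure + covariates            -> a1
3. outcome model:   outcome  ~ exposure + mediator
                               [+ exposure:mediator] + covariates -> b1, b3
4. indirect effect: a1 * (b1 + b3 * x) at each fixed exposure level x,
   with a Monte Carlo confidence interval built by sampling a1 from its
   estimated normal sampling distribution and (b1, b3) jointly from the
   outcome-model multivariate normal, independently of a1.

The direct effect is the total minus the indirect effect, so the
decomposition identity direct + indirect = c1 holds exactly per level. When
a significant exposure-mediator interaction is found on a continuous
adiposity exposure, the exposure is dichotomised at the conventional cut
(BMI 25 kg/m^2, closed above; FMI 9, open above) and effects are reported
at both levels. One shared complete-case set is enforced across all steps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lmm import ModelFit, ModelSpec, fit_lmm, wald_p
from .preprocess import AdiposityThresholds

__all__ = [
    "MediationSpec",
    "MediationResult",
    "run_mediation",
    "decompose",
    "monte_carlo_ci",
    "screen_and_dichotomize",
    "dichotomize_exposure",
]


@dataclass(frozen=True)
class MediationSpec:
    """What to mediate: exposure, mediator, outcome and model context."""

    exposure: str
    mediator: str
    outcome: str
    covariates: tuple[str, ...] = ()
    exposure_mediator_interaction: bool = False
    exposure_levels: tuple[float, float] = (0.0, 1.0)
    level_labels: tuple[str, str] = ("reference", "index")
    n_draws: int = 20_000
    ci_level: float = 0.95
    grouping: str = "dyad_id"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_draws < 1_000:
            raise ValueError("n_draws must be at least 1,000")
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError("ci_level must be in (0, 1)")


@dataclass
class LevelEffects:
    """Effect decomposition at one fixed exposure level."""

    level: float
    indirect: float
    direct: float
    proportion_mediated: float | None
    mc_ci: tuple[float, float]
    mc_p: float
    indirect_significant: bool


@dataclass
class MediationResult:
    c1: float
    a1: float
    b1: float
    b3: float
    p_c1: float
    p_a1: float
    p_b1: float
    p_interaction: float | None
    levels: dict[str, LevelEffects]
    n_complete: int
    n_total_effect: int
    seed: int | None
    spec: MediationSpec
    step_fits: dict[str, ModelFit] = field(default_factory=dict)

    def to_json(self) -> str:
        d = {
            "c1": self.c1, "a1": self.a1, "b1": self.b1, "b3": self.b3,
            "p_c1": self.p_c1, "p_a1": self.p_a1, "p_b1": self.p_b1,
            "p_interaction": self.p_interaction,
            "n_complete": self.n_complete,
            "n_total_effect": self.n_total_effect,
            "seed": self.seed,
            "exposure": self.spec.exposure,
            "mediator": self.spec.mediator,
            "outcome": self.spec.outcome,
            "covariates": list(self.spec.covariates),
            "n_draws": self.spec.n_draws,
            "ci_level": self.spec.ci_level,
            "levels": {
                k: {
                    "level": v.level, "indirect": v.indirect, "direct": v.direct,
                    "proportion_mediated": v.proportion_mediated,
                    "mc_ci": list(v.mc_ci), "mc_p": v.mc_p,
                    "indirect_significant": v.indirect_significant,
                }
                for k, v in self.levels.items()
            },
            "step_fits": {k: json.loads(f.to_json()) for k, f in self.step_fits.items()},
        }
        return json.dumps(d)


def decompose(
    a1: float, b1: float, b3: float, c1: float, level_x: float
) -> tuple[float, float, float | None]:
    """Indirect/direct/proportion-mediated at a fixed exposure level.

    indirect = a1 * (b1 + b3 * x); direct = c1 - indirect; proportion
    mediated = 100 * indirect / c1 (None when the total effect is zero).
    """
    indirect = a1 * (b1 + b3 * level_x)
    direct = c1 - indirect
    pm = None if c1 == 0 else 100.0 * indirect / c1
    return indirect, direct, pm


def _psd_factor(v: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    v = np.atleast_2d(np.asarray(v, dtype=float))
    if not np.allclose(v, v.T, atol=1e-8):
        raise ValueError("covariance matrix must be symmetric")
    w, q = np.linalg.eigh(v)
    if w.min() < -tol * max(1.0, abs(w).max()):
        raise ValueError("covariance matrix must be positive semi-definite")
    return q * np.sqrt(np.clip(w, 0.0, None))


def monte_carlo_ci(
    a_hat: float,
    vcov_a: float | np.ndarray,
    b_vec_hat: float | np.ndarray,
    vcov_b: float | np.ndarray,
    level_x: float = 0.0,
    n_draws: int = 20_000,
    ci_level: float = 0.95,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """Monte Carlo CI for the product-of-coefficients indirect effect.

    Draws ``a*`` from Normal(a_hat, vcov_a) and ``(b1*, b3*)`` jointly from
    the outcome-model multivariate normal (independently of ``a*``, since
    the two models are fit separately), forms ``a* (b1* + b3* x)`` per draw
    and returns the percentile interval at ``ci_level`` together with a
    two-sided Monte Carlo p-value against zero.
    """
    if n_draws < 1_000:
        raise ValueError("n_draws must be at least 1,000")
    if rng is None:
        rng = np.random.default_rng(seed)
    var_a = float(np.atleast_2d(np.asarray(vcov_a, dtype=float))[0, 0])
    if var_a < 0:
        raise ValueError("variance of a must be non-negative")
    b = np.atleast_1d(np.asarray(b_vec_hat, dtype=float))
    fac = _psd_factor(vcov_b)
    a_draws = a_hat + np.sqrt(var_a) * rng.standard_normal(n_draws)
    b_draws = b + rng.standard_normal((n_draws, len(b))) @ fac.T
    slope = b_draws[:, 0]
    if len(b) > 1:
        slope = slope + b_draws[:, 1] * level_x
    ind = a_draws * slope
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(ind, [alpha / 2.0, 1.0 - alpha / 2.0])
    p = 2.0 * min(np.mean(ind <= 0.0), np.mean(ind >= 0.0))
    return float(lo), float(hi), float(min(p, 1.0))


def dichotomize_exposure(
    data: pd.DataFrame,
    exposure: str,
    thresholds: AdiposityThresholds | None = None,
) -> tuple[pd.DataFrame, str, tuple[str, str]]:
    """Add a 0/1 adiposity-group column for a continuous exposure.

    BMI-type exposures use the closed >= 25 kg/m^2 bound ('overweight');
    FMI-type exposures the open > 9 bound ('excessive'). Returns the
    augmented data, the new column name and the level labels.
    """
    th = thresholds or AdiposityThresholds()
    out = data.copy()
    if "fmi" in exposure.lower():
        col = f"{exposure}_excessive"
        out[col] = (out[exposure] > th.fmi_cut).astype(float).mask(out[exposure].isna())
        labels = ("normal", "excessive")
    else:
        col = f"{exposure}_overweight"
        out[col] = (out[exposure] >= th.bmi_cut).astype(float).mask(out[exposure].isna())
        labels = ("normal", "overweight")
    return out, col, labels


def screen_and_dichotomize(
    data: pd.DataFrame,
    spec: MediationSpec,
    thresholds: AdiposityThresholds | None = None,
    alpha: float = 0.05,
) -> tuple[MediationSpec, pd.DataFrame, float]:
    """Interaction screen on a continuous exposure.

    Tests the exposure x mediator term in the step-3 outcome model. When
    significant, returns a spec with the exposure dichotomised at the
    conventional adiposity cut and the interaction retained; otherwise the
    continuous, interaction-free spec. Also returns the (possibly
    augmented) data and the screening p-value.
    """
    vals = data[spec.exposure].dropna().unique()
    if set(np.unique(vals)) <= {0.0, 1.0}:
        raise ValueError("exposure is already categorical; nothing to screen")
    step3 = ModelSpec(
        outcome=spec.outcome,
        fixed_terms=(spec.exposure, spec.mediator) + spec.covariates,
        grouping=spec.grouping,
        interactions=((spec.exposure, spec.mediator),),
    )
    fit = fit_lmm(data, step3)
    name = f"{spec.exposure}:{spec.mediator}"
    if name not in fit.coef.index:
        name = f"{spec.mediator}:{spec.exposure}"
    p = fit.p_value(name)
    if p >= alpha:
        return spec, data, p
    aug, col, labels = dichotomize_exposure(data, spec.exposure, thresholds)
    new_spec = MediationSpec(
        exposure=col,
        mediator=spec.mediator,
        outcome=spec.outcome,
        covariates=spec.covariates,
        exposure_mediator_interaction=True,
        exposure_levels=(0.0, 1.0),
        level_labels=labels,
        n_draws=spec.n_draws,
        ci_level=spec.ci_level,
        grouping=spec.grouping,
        seed=spec.seed,
    )
    return new_spec, aug, p


def run_mediation(data: pd.DataFrame, spec: MediationSpec) -> MediationResult:
    """Full four-step mediation on one exposure/mediator/outcome triple.

    All three models are fit on ONE complete-case set (rows complete for
    every variable used in any step), so the decomposition identity holds
    across steps; the total-effect model is additionally reported on its
    own, larger complete-case set (``n_total_effect``).
    """
    import re

    used = " ".join(
        [spec.exposure, spec.mediator, spec.outcome, spec.grouping, *spec.covariates]
    )
    names = set(re.findall(r"[A-Za-z_][A-Za-z0-9_]*", used))
    cols = [c for c in data.columns if c in names]
    complete = data.dropna(subset=cols)

    step1 = ModelSpec(
        outcome=spec.outcome,
        fixed_terms=(spec.exposure,) + spec.covariates,
        grouping=spec.grouping,
    )
    step2 = ModelSpec(
        outcome=spec.mediator,
        fixed_terms=(spec.exposure,) + spec.covariates,
        grouping=spec.grouping,
    )
    interactions = (
        ((spec.exposure, spec.mediator),) if spec.exposure_mediator_interaction else ()
    )
    step3 = ModelSpec(
        outcome=spec.outcome,
        fixed_terms=(spec.exposure, spec.mediator) + spec.covariates,
        grouping=spec.grouping,
        interactions=interactions,
    )

    fit1 = fit_lmm(complete, step1)
    # the total-effect model runs on its own complete-case set, which can be
    # larger than the all-steps set; skip the refit when they coincide
    n_step1 = len(data.dropna(subset=[c for c in cols if c in step1.columns(data)]))
    fit_total_full = fit1 if n_step1 == len(complete) else fit_lmm(data, step1)
    fit2 = fit_lmm(complete, step2)
    fit3 = fit_lmm(complete, step3)

    c1 = float(fit1.coef[spec.exposure])
    a1 = float(fit2.coef[spec.exposure])
    b1 = float(fit3.coef[spec.mediator])
    p_inter = None
    if spec.exposure_mediator_interaction:
        iname = f"{spec.exposure}:{spec.mediator}"
        if iname not in fit3.coef.index:
            iname = f"{spec.mediator}:{spec.exposure}"
        b3 = float(fit3.coef[iname])
        b_names = [spec.mediator, iname]
        p_inter = fit3.p_value(iname)
    else:
        b3 = 0.0
        b_names = [spec.mediator]

    var_a = float(fit2.vcov.loc[spec.exposure, spec.exposure])
    vcov_b = fit3.vcov.loc[b_names, b_names].to_numpy()
    b_vec = np.array([b1] + ([b3] if len(b_names) > 1 else []))

    if spec.exposure_mediator_interaction:
        levels = dict(zip(spec.level_labels, spec.exposure_levels))
    else:
        levels = {"overall": 0.0}

    rng = np.random.default_rng(spec.seed)
    out_levels: dict[str, LevelEffects] = {}
    for label, x in levels.items():
        indirect, direct, pm = decompose(a1, b1, b3, c1, x)
        lo, hi, p = monte_carlo_ci(
            a1, var_a, b_vec, vcov_b,
            level_x=x, n_draws=spec.n_draws, ci_level=spec.ci_level, rng=rng,
        )
        out_levels[label] = LevelEffects(
            level=x, indirect=indirect, direct=direct, proportion_mediated=pm,
            mc_ci=(lo, hi), mc_p=p,
            indirect_significant=not (lo <= 0.0 <= hi),
        )

    return MediationResult(
        c1=c1, a1=a1, b1=b1, b3=b3,
        p_c1=fit1.p_value(spec.exposure),
        p_a1=fit2.p_value(spec.exposure),
        p_b1=fit3.p_value(spec.mediator),
        p_interaction=p_inter,
        levels=out_levels,
        n_complete=fit1.n_obs,
        n_total_effect=fit_total_full.n_obs,
        seed=spec.seed,
        spec=spec,
        step_fits={"total": fit_total_full, "step1": fit1, "step2": fit2, "step3": fit3},
    )
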