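"""Linear mixed models with a per-subject random intercept.

Thin, opinionated layer over statsmodels MixedLM for the repeated dyad-visit
design: every model carries a mother-level random intercept, fixed effects
are given as formula terms, coefficients are tested with Wald z statistics,
and log-scale estimates are back-transformed to percent differences for
reporting. Degenerate designs with one observation per subject reduce to
ordinary least squares.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "ModelSpec",
    "ModelFit",
    "fit_lmm",
    "test_interaction",
    "wald_p",
    "percent_difference",
    "effect_per_percent_increase",
    "visit_contrasts",
]


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one random-intercept model.

    ``fixed_terms`` are patsy-style terms (e.g. ``"maternal_bmi"``,
    ``"C(visit)"``); ``interactions`` are pairs of terms combined as
    ``a:b``. ``log_outcome`` applies a natural-log transform to the outcome
    column before fitting.
    """

    outcome: str
    fixed_terms: tuple[str, ...]
    grouping: str = "dyad_id"
    interactions: tuple[tuple[str, str], ...] = ()
    log_outcome: bool = False
    method: str = "REML"

    def __post_init__(self) -> None:
        if self.outcome in self.fixed_terms:
            raise ValueError("outcome cannot appear among fixed effects")
        for a, b in self.interactions:
            if a not in self.fixed_terms or b not in self.fixed_terms:
                raise ValueError(f"interaction members ({a}, {b}) must be fixed terms")
        if self.method not in ("REML", "ML"):
            raise ValueError("method must be REML or ML")

    @property
    def formula(self) -> str:
        rhs = list(self.fixed_terms) + [f"{a}:{b}" for a, b in self.interactions]
        lhs = f"np.log({self.outcome})" if self.log_outcome else self.outcome
        return f"{lhs} ~ " + (" + ".join(rhs) if rhs else "1")

    def columns(self, data: pd.DataFrame) -> list[str]:
        """Data columns referenced by the model (for complete-case filtering)."""
        names = set(re.findall(r"[A-Za-z_][A-Za-z0-9_]*", self.formula))
        cols = [c for c in data.columns if c in names]
        if self.grouping not in cols:
            cols.append(self.grouping)
        return cols


@dataclass
class ModelFit:
    """Fixed-effect estimates, their covariance and fit metadata."""

    coef: pd.Series
    vcov: pd.DataFrame
    n_obs: int
    n_subjects: int
    var_subject: float
    var_resid: float
    converged: bool
    formula: str
    method: str

    def se(self, name: str) -> float:
        return float(np.sqrt(self.vcov.loc[name, name]))

    def p_value(self, name: str) -> float:
        return wald_p(float(self.coef[name]), self.se(name))

    def to_json(self) -> str:
        return json.dumps(
            {
                "coef": self.coef.to_dict(),
                "vcov": {"index": list(self.vcov.index),
                         "values": self.vcov.to_numpy().tolist()},
                "n_obs": self.n_obs,
                "n_subjects": self.n_subjects,
                "var_subject": self.var_subject,
                "var_resid": self.var_resid,
                "converged": self.converged,
                "formula": self.formula,
                "method": self.method,
            }
        )


def wald_p(estimate: float, se: float) -> float:
    """Two-sided Wald p-value against a standard normal reference."""
    if se <= 0:
        return 0.0 if estimate != 0 else 1.0
    return float(2.0 * stats.norm.sf(abs(estimate) / se))


def fit_lmm(data: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Fit a fixed-effects + subject-random-intercept model.

    Complete cases only (rows missing any referenced column are dropped).
    REML is the default; when every subject contributes a single
    observation the random intercept is unidentifiable and the model is fit
    by ordinary least squares (zero subject variance). Rank-deficient
    designs raise; non-convergence is reported on the fit, never silent.
    """
    cols = spec.columns(data)
    d = data[cols].dropna()
    if spec.log_outcome:
        d = d[d[spec.outcome] > 0]
    groups = d[spec.grouping]
    n_subjects = groups.nunique()
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")

    max_per_subject = groups.value_counts().max()
    if max_per_subject == 1:
        model = smf.ols(spec.formula, data=d)
        _check_rank(model.exog, spec)
        res = model.fit()
        k = len(res.params)
        return ModelFit(
            coef=res.params, vcov=pd.DataFrame(
                res.cov_params(), index=res.params.index, columns=res.params.index
            ),
            n_obs=int(res.nobs), n_subjects=int(n_subjects),
            var_subject=0.0, var_resid=float(res.mse_resid),
            converged=True, formula=spec.formula, method="OLS",
        )

    model = smf.mixedlm(spec.formula, data=d, groups=groups)
    _check_rank(model.exog, spec)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            res = model.fit(reml=spec.method == "REML")
        except (ConvergenceWarning, np.linalg.LinAlgError):
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(reml=spec.method == "REML", method="powell")
    fe = res.fe_params
    k = len(fe)
    vc = np.asarray(res.cov_params())[:k, :k]
    # when the random-intercept variance is estimated on the zero boundary
    # the Hessian-based covariance can be invalid (negative diagonal);
    # at that boundary the model is exactly OLS, so fall back to it
    if not np.all(np.isfinite(np.diag(vc))) or np.any(np.diag(vc) <= 0):
        ols = smf.ols(spec.formula, data=d).fit()
        return ModelFit(
            coef=ols.params,
            vcov=pd.DataFrame(
                ols.cov_params(), index=ols.params.index, columns=ols.params.index
            ),
            n_obs=int(ols.nobs), n_subjects=int(n_subjects),
            var_subject=0.0, var_resid=float(ols.mse_resid),
            converged=True, formula=spec.formula, method="OLS",
        )
    return ModelFit(
        coef=pd.Series(fe, index=fe.index),
        vcov=pd.DataFrame(vc, index=fe.index, columns=fe.index),
        n_obs=int(model.nobs), n_subjects=int(n_subjects),
        var_subject=float(np.asarray(res.cov_re)[0, 0]),
        var_resid=float(res.scale),
        converged=converged, formula=spec.formula, method=spec.method,
    )


def _check_rank(exog: np.ndarray, spec: ModelSpec) -> None:
    exog = np.asarray(exog)
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise ValueError(f"rank-deficient design for model {spec.formula!r}")


def _interaction_name(fit: ModelFit, a: str, b: str) -> str:
    """Locate the design-matrix name of the a:b interaction column."""
    pat_a = re.escape(a)
    pat_b = re.escape(b)
    for name in fit.coef.index:
        if re.search(f"{pat_a}.*:.*{pat_b}", name) or re.search(
            f"{pat_b}.*:.*{pat_a}", name
        ):
            return name
    raise KeyError(f"no interaction {a}:{b} among coefficients {list(fit.coef.index)}")


def test_interaction(
    data: pd.DataFrame,
    spec: ModelSpec,
    term_pair: tuple[str, str],
    alpha: float = 0.05,
) -> tuple[float, bool]:
    """Wald test of an interaction coefficient added to ``spec``.

    Returns ``(p_value, p_value < alpha)``. Both members of the pair must
    already be fixed-effect terms of the model.
    """
    a, b = term_pair
    if a not in spec.fixed_terms or b not in spec.fixed_terms:
        raise ValueError(f"both interaction terms must be in the model: {term_pair}")
    if term_pair not in spec.interactions:
        spec = ModelSpec(
            outcome=spec.outcome,
            fixed_terms=spec.fixed_terms,
            grouping=spec.grouping,
            interactions=spec.interactions + (term_pair,),
            log_outcome=spec.log_outcome,
            method=spec.method,
        )
    fit = fit_lmm(data, spec)
    name = _interaction_name(fit, a, b)
    p = fit.p_value(name)
    return p, p < alpha


def percent_difference(beta: float) -> float:
    """Back-transform a natural-log-scale estimate to a percent difference.

    ``100 * (exp(beta) - 1)``: the percent change in the outcome's
    geometric mean per unit contrast on the modelled scale.
    """
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    return 100.0 * float(np.expm1(beta))


def effect_per_percent_increase(beta: float, pct: float) -> float:
    """Outcome change for a given percent increase of a log-scale exposure.

    For an outcome modelled on log-exposure with slope ``beta``, a ``pct``
    percent increase of the exposure shifts the outcome by
    ``beta * ln(1 + pct/100)``.
    """
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    if pct <= -100:
        raise ValueError("pct must exceed -100")
    return float(beta) * float(np.log1p(pct / 100.0))


def visit_contrasts(
    data: pd.DataFrame, hormone: str, compartment: str = "milk"
) -> pd.DataFrame:
    """Adjacent-visit change in log hormone concentration.

    Fits log concentration on visit (categorical), infant sex and per-visit
    centred age with a subject random intercept, then returns each
    adjacent-visit contrast with its standard error, Wald p-value and
    back-transformed percent difference. The random-intercept covariance is
    a simplification relative to an unstructured longitudinal covariance,
    but targets the same mean trajectory.
    """
    col = f"{compartment}_{hormone}"
    if col not in data.columns:
        raise KeyError(f"no column {col!r} in data")
    d = data.dropna(subset=[col, "visit", "infant_sex", "infant_age_months"])
    visits = sorted(d["visit"].unique())
    if len(visits) < 2:
        raise ValueError("need data from at least two visits")
    if "centered_age" not in d.columns:
        from .preprocess import center_age

        d = center_age(d)
    spec = ModelSpec(
        outcome=col,
        fixed_terms=("C(visit)", "infant_sex", "centered_age"),
        log_outcome=True,
    )
    fit = fit_lmm(d, spec)
    base = visits[0]
    betas = {base: 0.0}
    names = {base: None}
    for v in visits[1:]:
        name = f"C(visit)[T.{v}]"
        betas[v] = float(fit.coef[name])
        names[v] = name
    rows = []
    for prev, cur in zip(visits[:-1], visits[1:]):
        est = betas[cur] - betas[prev]
        var = 0.0
        for v, sign in ((cur, 1), (prev, 1)):
            if names[v] is not None:
                var += fit.vcov.loc[names[v], names[v]]
        if names[prev] is not None and names[cur] is not None:
            var -= 2.0 * fit.vcov.loc[names[prev], names[cur]]
        se = float(np.sqrt(max(var, 0.0)))
        rows.append(
            {
                "contrast": f"{prev}->{cur}",
                "beta": est,
                "se": se,
                "p": wald_p(est, se),
                "percent_difference": percent_difference(est),
            }
        )
    return pd.DataFrame(rows)
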