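import numpy as np
import pandas as pd
import pytest

from milktriad.lmm import (
    ModelSpec,
    effect_per_percent_increase,
    fit_lmm,
    percent_difference,
    visit_contrasts,
)
from milktriad.lmm import test_interaction as interaction_test  # avoid pytest collection
from milktriad.synthetic import CohortParams, generate_cohort
from milktriad.preprocess import preprocess_visit_table

NO_DROPOUT = {"V1": 0.0, "V2": 1.0, "V3": 1.0, "V4": 1.0}


def gls_oracle(y, X, groups, var_subject, var_resid):
    """Closed-form GLS coefficients given known variance components."""
    n = len(y)
    V = var_resid * np.eye(n)
    for g in np.unique(groups):
        idx = np.where(groups == g)[0]
        V[np.ix_(idx, idx)] += var_subject
    Vi = np.linalg.inv(V)
    return np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)


class TestFitLmm:
    def test_constant_outcome_intercept_only(self):
        d = pd.DataFrame({"y": [5.0] * 6, "dyad_id": range(6)})
        fit = fit_lmm(d, ModelSpec(outcome="y", fixed_terms=()))
        assert fit.coef["Intercept"] == pytest.approx(5.0)
        assert fit.var_resid == pytest.approx(0.0, abs=1e-12)
        assert fit.method == "OLS"

    def test_single_obs_per_subject_equals_ols(self, rng):
        n = 40
        d = pd.DataFrame(
            {
                "x": rng.normal(size=n),
                "z": rng.normal(size=n),
                "dyad_id": np.arange(n),
            }
        )
        d["y"] = 1.0 + 2.0 * d.x - 0.5 * d.z + rng.normal(0, 0.3, n)
        fit = fit_lmm(d, ModelSpec(outcome="y", fixed_terms=("x", "z")))
        X = np.column_stack([np.ones(n), d.x, d.z])
        beta = np.linalg.solve(X.T @ X, X.T @ d.y)
        assert np.allclose(fit.coef[["Intercept", "x", "z"]], beta, rtol=1e-6)

    def test_matches_gls_oracle_on_balanced_toy(self, rng):
        n_subj, n_vis = 15, 3
        g = np.repeat(np.arange(n_subj), n_vis)
        x = rng.normal(size=n_subj * n_vis)
        u = rng.normal(0, 0.8, n_subj)[g]
        y = 0.5 + 1.5 * x + u + rng.normal(0, 0.5, n_subj * n_vis)
        d = pd.DataFrame({"y": y, "x": x, "dyad_id": g})
        fit = fit_lmm(d, ModelSpec(outcome="y", fixed_terms=("x",)))
        beta = gls_oracle(
            y, np.column_stack([np.ones(len(y)), x]), g,
            fit.var_subject, fit.var_resid,
        )
        assert np.allclose(fit.coef[["Intercept", "x"]], beta, rtol=1e-4)

    def test_recovers_generating_slope(self, structured_cohort):
        table, _, truth = structured_cohort
        spec = ModelSpec(
            outcome="log_plasma_leptin",
            fixed_terms=("maternal_bmi", "C(visit)"),
        )
        fit = fit_lmm(table, spec)
        est = fit.coef["maternal_bmi"]
        assert abs(est - truth.a1) < 3 * fit.se("maternal_bmi")

    def test_rank_deficient_design_rejected(self, rng):
        n = 30
        g = np.repeat(np.arange(10), 3)
        x = rng.normal(size=n)
        d = pd.DataFrame({"y": rng.normal(size=n), "x": x, "x2": 2 * x, "dyad_id": g})
        with pytest.raises(ValueError, match="rank"):
            fit_lmm(d, ModelSpec(outcome="y", fixed_terms=("x", "x2")))

    def test_outcome_in_fixed_terms_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(outcome="y", fixed_terms=("y", "x"))

    def test_orthogonal_covariate_leaves_estimates_unchanged(self, rng):
        n_subj, n_vis = 20, 3
        g = np.repeat(np.arange(n_subj), n_vis)
        x = rng.normal(size=n_subj * n_vis)
        z = rng.normal(size=n_subj * n_vis)
        z = z - np.polyval(np.polyfit(x, z, 1), x)  # orthogonalise to x
        y = 1.0 + 0.7 * x + rng.normal(0, 0.4, n_subj)[g] + rng.normal(
            0, 0.4, n_subj * n_vis
        )
        d = pd.DataFrame({"y": y, "x": x, "z": z, "dyad_id": g})
        f1 = fit_lmm(d, ModelSpec(outcome="y", fixed_terms=("x",)))
        f2 = fit_lmm(d, ModelSpec(outcome="y", fixed_terms=("x", "z")))
        assert f1.coef["x"] == pytest.approx(f2.coef["x"], abs=0.02)


class TestInteraction:
    def _simulate(self, rng, b3):
        n_subj, n_vis = 80, 3
        g = np.repeat(np.arange(n_subj), n_vis)
        x = rng.normal(size=n_subj)[g]
        m = rng.normal(size=n_subj * n_vis)
        y = (
            0.3 * x + 0.5 * m + b3 * x * m
            + rng.normal(0, 0.5, n_subj)[g]
            + rng.normal(0, 0.5, n_subj * n_vis)
        )
        return pd.DataFrame({"y": y, "x": x, "m": m, "dyad_id": g})

    def test_type_i_error_rate(self, rng):
        spec = ModelSpec(outcome="y", fixed_terms=("x", "m"))
        rejections = 0
        n_reps = 300
        for _ in range(n_reps):
            d = self._simulate(rng, b3=0.0)
            _, sig = interaction_test(d, spec, ("x", "m"))
            rejections += sig
        rate = rejections / n_reps
        assert 0.03 <= rate <= 0.07  # nominal 5% within simulation error

    def test_power_on_large_interaction(self, rng):
        spec = ModelSpec(outcome="y", fixed_terms=("x", "m"))
        d = self._simulate(rng, b3=0.5)
        p, sig = interaction_test(d, spec, ("x", "m"))
        assert sig and p < 1e-4

    def test_term_absent_rejected(self, rng):
        d = self._simulate(rng, 0.0)
        spec = ModelSpec(outcome="y", fixed_terms=("x",))
        with pytest.raises(ValueError):
            interaction_test(d, spec, ("x", "m"))


class TestBackTransforms:
    @pytest.mark.parametrize(
        "beta,expected",
        [(-0.78, -54.16), (0.0, 0.0), (1.6, 395.30), (np.log(2), 100.0)],
    )
    def test_percent_difference(self, beta, expected):
        assert percent_difference(beta) == pytest.approx(expected, abs=0.01)

    @pytest.mark.parametrize(
        "beta,pct,expected",
        [(140.2, 10, 13.363), (-89.8, 10, -8.559), (42.0, 0, 0.0)],
    )
    def test_effect_per_percent_increase(self, beta, pct, expected):
        assert effect_per_percent_increase(beta, pct) == pytest.approx(
            expected, abs=0.001
        )

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            percent_difference(float("nan"))
        with pytest.raises(ValueError):
            effect_per_percent_increase(1.0, -100.0)


class TestVisitContrasts:
    def test_halving_per_visit(self):
        p = CohortParams(n_dyads=300, seed=19, lod_censor=False, dropout=dict(NO_DROPOUT))
        for v, med in zip(("V1", "V2", "V3", "V4"), (400.0, 200.0, 100.0, 50.0)):
            p.hormone_medians["milk_insulin"][v] = med
        visits, _, _ = generate_cohort(p)
        table = preprocess_visit_table(visits)
        out = visit_contrasts(table, "insulin", "milk")
        for _, row in out.iterrows():
            assert abs(row.beta - (-np.log(2))) < 3 * row.se
        # halving is a 50% decrease after back-transformation
        assert out.percent_difference.iloc[0] == pytest.approx(-50.0, abs=8.0)

    def test_single_visit_rejected(self, structured_cohort):
        table, _, _ = structured_cohort
        with pytest.raises(ValueError):
            visit_contrasts(table[table.visit == "V2"], "leptin", "milk")
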