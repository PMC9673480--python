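import numpy as np
import pandas as pd
import pytest
from scipy import stats

from milktriad.lmm import ModelSpec, fit_lmm
from milktriad.mediate import (
    MediationSpec,
    decompose,
    dichotomize_exposure,
    monte_carlo_ci,
    run_mediation,
    screen_and_dichotomize,
)


class TestDecompose:
    def test_simple_product(self):
        ind, direct, pm = decompose(a1=0.5, b1=0.8, b3=0.0, c1=0.6, level_x=0.0)
        assert ind == pytest.approx(0.40)
        assert direct == pytest.approx(0.20)
        assert pm == pytest.approx(100 * 0.40 / 0.6)

    def test_direct_share_example(self):
        # indirect 0.0039 against a total of 0.0249 leaves ~84% direct
        ind, direct, pm = decompose(0.039, 0.1, 0.0, 0.0249, 0.0)
        assert ind == pytest.approx(0.0039)
        assert direct == pytest.approx(0.021)
        assert 100 * direct / 0.0249 == pytest.approx(84.34, abs=0.01)

    def test_proportion_mediated_example(self):
        # indirect 0.81 of a 1.6 total is ~51% mediated
        ind, _, pm = decompose(0.9, 0.9, 0.0, 1.6, 0.0)
        assert ind == pytest.approx(0.81)
        assert pm == pytest.approx(50.625)

    def test_interaction_level_dependence(self):
        ind0, _, _ = decompose(0.5, 0.8, 0.3, 1.0, 0.0)
        ind1, _, _ = decompose(0.5, 0.8, 0.3, 1.0, 1.0)
        assert ind0 == pytest.approx(0.40)
        assert ind1 == pytest.approx(0.5 * 1.1)

    def test_identity_direct_plus_indirect_is_total(self):
        for x in (0.0, 1.0, -2.3):
            ind, direct, _ = decompose(0.37, -0.2, 0.15, 0.55, x)
            assert ind + direct == pytest.approx(0.55, abs=1e-12)

    def test_zero_total_gives_no_proportion(self):
        _, _, pm = decompose(0.5, 0.8, 0.0, 0.0, 0.0)
        assert pm is None


class TestMonteCarloCI:
    def test_degenerate_variances_collapse(self):
        lo, hi, _ = monte_carlo_ci(6.0, 0.0, 1.0, 0.0, seed=1)
        assert lo == pytest.approx(6.0)
        assert hi == pytest.approx(6.0)

    def test_null_is_symmetric_and_nonsignificant(self):
        lo, hi, p = monte_carlo_ci(0.0, 1.0, 0.0, 1.0, n_draws=200_000, seed=2)
        assert lo < 0 < hi
        assert abs(lo + hi) < 0.05  # symmetric product-of-normals null
        assert p > 0.5

    def test_matches_normal_theory_when_one_factor_is_precise(self):
        # with var(a) -> 0 the indirect draws are a * N(b, vb): exact quantiles
        a, b, vb = 2.0, 0.5, 0.04
        lo, hi, _ = monte_carlo_ci(a, 0.0, b, vb, n_draws=400_000, seed=3)
        z = stats.norm.ppf(0.975)
        assert lo == pytest.approx(a * (b - z * np.sqrt(vb)), abs=0.01)
        assert hi == pytest.approx(a * (b + z * np.sqrt(vb)), abs=0.01)

    def test_interaction_level_shifts_interval(self):
        vb = np.diag([0.01, 0.01])
        lo0, hi0, _ = monte_carlo_ci(0.5, 1e-6, [0.8, 0.4], vb, level_x=0.0, seed=4)
        lo1, hi1, _ = monte_carlo_ci(0.5, 1e-6, [0.8, 0.4], vb, level_x=1.0, seed=4)
        assert (lo1 + hi1) / 2 > (lo0 + hi0) / 2

    def test_seed_reproducible(self):
        r1 = monte_carlo_ci(0.5, 0.01, 0.8, 0.02, seed=11)
        r2 = monte_carlo_ci(0.5, 0.01, 0.8, 0.02, seed=11)
        assert r1 == r2

    def test_validation(self):
        with pytest.raises(ValueError, match="n_draws"):
            monte_carlo_ci(0.5, 0.01, 0.8, 0.02, n_draws=10, seed=1)
        with pytest.raises(ValueError):
            monte_carlo_ci(0.5, -0.01, 0.8, 0.02, seed=1)
        with pytest.raises(ValueError, match="symmetric"):
            monte_carlo_ci(0.5, 0.01, [0.8, 0.1], [[0.02, 0.5], [0.0, 0.02]], seed=1)
        with pytest.raises(ValueError, match="semi-definite"):
            monte_carlo_ci(0.5, 0.01, [0.8, 0.1], [[1.0, 2.0], [2.0, 1.0]], seed=1)


class TestDichotomize:
    def test_bmi_closed_bound(self):
        d = pd.DataFrame({"maternal_bmi": [24.9, 25.0, 30.0, np.nan]})
        out, col, labels = dichotomize_exposure(d, "maternal_bmi")
        assert col == "maternal_bmi_overweight"
        assert labels == ("normal", "overweight")
        assert out[col].tolist()[:3] == [0.0, 1.0, 1.0]
        assert np.isnan(out[col].iloc[3])

    def test_fmi_open_bound(self):
        d = pd.DataFrame({"maternal_fmi": [9.0, 9.01]})
        out, col, labels = dichotomize_exposure(d, "maternal_fmi")
        assert col == "maternal_fmi_excessive"
        assert labels == ("normal", "excessive")
        assert out[col].tolist() == [0.0, 1.0]


class TestScreen:
    def _make(self, rng, b3, n_subj=150):
        g = np.repeat(np.arange(n_subj), 3)
        x = rng.uniform(20, 32, n_subj)[g]  # BMI-like exposure
        m = rng.normal(size=n_subj * 3)
        y = (
            0.02 * x + 0.5 * m + b3 * (x - 25) * m
            + rng.normal(0, 0.4, n_subj)[g]
            + rng.normal(0, 0.4, n_subj * 3)
        )
        return pd.DataFrame({"y": y, "maternal_bmi": x, "m": m, "dyad_id": g})

    def test_null_keeps_continuous_spec(self, rng):
        d = self._make(rng, b3=0.0)
        spec = MediationSpec(exposure="maternal_bmi", mediator="m", outcome="y")
        new, data, p = screen_and_dichotomize(d, spec, alpha=0.001)
        assert new is spec
        assert not new.exposure_mediator_interaction
        assert data is d

    def test_strong_interaction_dichotomizes(self, rng):
        d = self._make(rng, b3=0.4)
        spec = MediationSpec(exposure="maternal_bmi", mediator="m", outcome="y")
        new, data, p = screen_and_dichotomize(d, spec)
        assert p < 0.05
        assert new.exposure == "maternal_bmi_overweight"
        assert new.exposure_mediator_interaction
        assert new.level_labels == ("normal", "overweight")
        assert "maternal_bmi_overweight" in data.columns

    def test_already_categorical_rejected(self, rng):
        d = self._make(rng, 0.0)
        d["grp"] = (d.maternal_bmi >= 25).astype(float)
        spec = MediationSpec(exposure="grp", mediator="m", outcome="y")
        with pytest.raises(ValueError, match="categorical"):
            screen_and_dichotomize(d, spec)


class TestRunMediation:
    def test_spec_validation(self):
        with pytest.raises(ValueError):
            MediationSpec(exposure="x", mediator="m", outcome="y", n_draws=100)
        with pytest.raises(ValueError):
            MediationSpec(exposure="x", mediator="m", outcome="y", ci_level=1.5)

    def test_ols_path_direct_equals_step3_exposure_coef(self, rng):
        # one row per dyad: pure OLS; direct effect must equal the step-3
        # exposure coefficient to numerical precision (linear-model identity)
        n = 200
        x = rng.normal(size=n)
        m = 0.5 * x + rng.normal(0, 0.6, n)
        y = 0.2 * x + 0.8 * m + rng.normal(0, 0.6, n)
        d = pd.DataFrame({"x": x, "m": m, "y": y, "dyad_id": np.arange(n)})
        spec = MediationSpec(exposure="x", mediator="m", outcome="y", seed=5)
        res = run_mediation(d, spec)
        fit3 = fit_lmm(d, ModelSpec(outcome="y", fixed_terms=("x", "m")))
        assert res.levels["overall"].direct == pytest.approx(
            float(fit3.coef["x"]), abs=1e-8
        )
        assert res.levels["overall"].indirect == pytest.approx(
            res.a1 * res.b1, abs=1e-12
        )

    def test_recovery_on_structured_cohort(self, structured_cohort):
        table, _, truth = structured_cohort
        spec = MediationSpec(
            exposure="maternal_bmi",
            mediator="log_plasma_leptin",
            outcome="log_milk_leptin",
            covariates=("C(visit)",),
            n_draws=5_000,
            seed=17,
        )
        res = run_mediation(table, spec)
        eff = res.levels["overall"]
        true_ind = truth.a1 * truth.b1
        half_width = (eff.mc_ci[1] - eff.mc_ci[0]) / 2
        # point estimate within 1.5 CI half-widths (~3 SEs) of the truth
        assert abs(eff.indirect - true_ind) < 1.5 * half_width
        assert eff.indirect_significant
        assert res.p_a1 < 1e-6 and res.p_b1 < 1e-6

    def test_shared_complete_case_set(self, rng):
        n = 120
        d = pd.DataFrame(
            {
                "x": rng.normal(size=n),
                "m": rng.normal(size=n),
                "y": rng.normal(size=n),
                "dyad_id": np.arange(n),
            }
        )
        d.loc[:19, "m"] = np.nan  # mediator missing for 20 rows
        res = run_mediation(
            d, MediationSpec(exposure="x", mediator="m", outcome="y", seed=1)
        )
        assert res.n_complete == 100
        assert res.n_total_effect == 120  # total-effect model keeps those rows

    def test_seeded_result_reproducible(self, rng):
        n = 80
        d = pd.DataFrame(
            {
                "x": rng.normal(size=n),
                "m": rng.normal(size=n),
                "y": rng.normal(size=n),
                "dyad_id": np.arange(n),
            }
        )
        spec = MediationSpec(exposure="x", mediator="m", outcome="y", seed=9)
        r1 = run_mediation(d, spec)
        r2 = run_mediation(d, spec)
        assert r1.to_json() == r2.to_json()

    def test_interaction_reports_both_levels(self, rng):
        n_subj = 120
        g = np.repeat(np.arange(n_subj), 2)
        x = rng.integers(0, 2, n_subj).astype(float)[g]
        m = 0.4 * x + rng.normal(0, 0.5, n_subj * 2)
        y = 0.1 * x + (0.6 + 0.5 * x) * m + rng.normal(0, 0.5, n_subj * 2)
        d = pd.DataFrame({"x": x, "m": m, "y": y, "dyad_id": g})
        spec = MediationSpec(
            exposure="x", mediator="m", outcome="y",
            exposure_mediator_interaction=True,
            level_labels=("normal", "overweight"), seed=3,
        )
        res = run_mediation(d, spec)
        assert set(res.levels) == {"normal", "overweight"}
        assert res.p_interaction is not None
        # indirect at the index level includes the interaction slope
        assert res.levels["overweight"].indirect == pytest.approx(
            res.a1 * (res.b1 + res.b3), abs=1e-12
        )
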