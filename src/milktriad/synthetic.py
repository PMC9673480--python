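"""Seeded synthetic longitudinal mother-infant dyad cohorts.

Generates dyad-visit tables and 24-h feed logs whose marginal distributions
mimic a Danish lactation cohort (right-skewed hormone concentrations with
visit-specific medians, maternal BMI around 23.6 kg/m^2 drifting down across
visits, infant growth by sex and visit), with a *known* log-scale mediation
structure injected on top:

    log M = log(median_M[visit]) + a1 * Xc + u_i + eps
    log Y = log(median_Y[visit]) + c1' * Xc + b1 * Mc + b3 * Xc * Mc
            + covariate effects + v_i + eps'

where X is maternal BMI (Xc centred at its mean), M the maternal plasma
concentration of the designated hormone, Y its milk concentration, Mc the
structural deviation of log M from its visit median, and u_i, v_i per-mother
random intercepts. A second, configurable pathway links log milk hormone ->
log infant plasma hormone -> infant weight for the infant-outcome analyses.

The generating parameters are returned alongside the data (`CohortTruth`)
so parameter-recovery and coverage tests can compare estimates against the
values actually used.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import HORMONE_COLUMNS, AssayConfig
from .weighing import FeedEvent, FeedLog

__all__ = [
    "ExposureDist",
    "InfantEffects",
    "CohortParams",
    "CohortTruth",
    "generate_cohort",
    "generate_feed_log",
    "write_cohort",
    "read_truth",
]

HORMONES = ("leptin", "insulin", "adiponectin")

#: per-visit medians in reporting units (milk leptin/insulin pg/mL,
#: milk adiponectin ng/mL, plasma leptin ng/mL, plasma insulin pg/mL,
#: plasma adiponectin ug/mL)
DEFAULT_MEDIANS: dict[str, dict[str, float]] = {
    "milk_leptin": {"V1": 419.0, "V2": 90.0, "V3": 48.0, "V4": 33.0},
    "milk_insulin": {"V1": 416.0, "V2": 202.0, "V3": 218.0, "V4": 211.0},
    "milk_adiponectin": {"V1": 8.2, "V2": 2.4, "V3": 1.9, "V4": 2.0},
    "plasma_leptin": {"V2": 4.7, "V3": 4.3, "V4": 5.1},
    "plasma_insulin": {"V2": 131.0, "V3": 163.0, "V4": 127.0},
    "plasma_adiponectin": {"V2": 4.4, "V3": 7.0, "V4": 4.0},
    "infant_plasma_leptin": {"V2": 2.7, "V3": 1.7, "V4": 2.2},
    "infant_plasma_insulin": {"V2": 135.0, "V3": 80.0, "V4": 100.0},
    "infant_plasma_adiponectin": {"V2": 23.6, "V3": 19.1, "V4": 10.2},
}

#: marginal natural-log-scale dispersion per hormone column (IQR-derived)
DEFAULT_LOG_SD: dict[str, float] = {
    "milk_leptin": 1.2,
    "milk_insulin": 0.4,
    "milk_adiponectin": 0.6,
    "plasma_leptin": 1.0,
    "plasma_insulin": 0.45,
    "plasma_adiponectin": 0.45,
    "infant_plasma_leptin": 0.8,
    "infant_plasma_insulin": 0.5,
    "infant_plasma_adiponectin": 0.35,
}

#: mean (SD) of visit ages in months
VISIT_AGE = {"V2": (2.1, 0.7), "V3": (4.6, 0.8), "V4": (7.1, 0.7)}
VISIT_BOUNDS = {"V2": (1.0, 3.49), "V3": (3.5, 5.99), "V4": (6.0, 8.5)}

#: infant growth by (variable, sex): per-visit means and a common SD
GROWTH = {
    ("infant_weight_g", "male"): ([5820.0, 7570.0, 8730.0], 800.0),
    ("infant_weight_g", "female"): ([5210.0, 6880.0, 8110.0], 900.0),
    ("infant_length_cm", "male"): ([60.1, 67.0, 70.8], 2.6),
    ("infant_length_cm", "female"): ([58.2, 64.7, 68.9], 2.6),
    ("infant_fmi", "male"): ([3.5, 4.1, 4.8], 0.9),
    ("infant_fmi", "female"): ([3.5, 4.4, 5.3], 1.0),
    ("infant_bodyfat_pct", "male"): ([21.7, 24.1, 27.3], 3.5),
    ("infant_bodyfat_pct", "female"): ([22.8, 27.0, 30.7], 4.0),
}

#: total 24-h milk intake means (mL) by sex across V2-V4
INTAKE_MEANS = {
    "male": [813.0, 844.0, 641.0],
    "female": [761.0, 840.0, 600.0],
}
INTAKE_SD = 180.0

MILK_ENERGY = {"V2": (633.0, 102.0), "V3": (615.0, 110.0), "V4": (615.0, 143.0)}


@dataclass(frozen=True)
class ExposureDist:
    """Maternal adiposity generation: BMI once per mother with small
    per-visit drift; FMI as a linear map of BMI plus noise."""

    bmi_mean: float = 23.6
    bmi_sd: float = 3.0
    visit_drift: float = -0.45  # kg/m^2 per visit after V2
    within_visit_sd: float = 0.3
    fmi_intercept: float = -7.26
    fmi_slope: float = 0.6
    fmi_sd: float = 0.8
    height_mean_m: float = 1.69
    height_sd_m: float = 0.06


@dataclass(frozen=True)
class InfantEffects:
    """Log-scale pathway from milk hormone to infant plasma to infant
    weight (grams); all zero by default (no infant-side structure)."""

    a1: float = 0.0  # log infant plasma per log milk hormone
    b1: float = 0.0  # grams infant weight per log infant plasma
    b3: float = 0.0
    c1_prime: float = 0.0  # grams infant weight per log milk hormone


@dataclass
class CohortParams:
    """All knobs of the synthetic cohort; defaults are the study conditions.

    The mediation structure (a1, b1, b3, c1_prime) applies to
    ``mediation_hormone`` in the maternal pathway BMI -> plasma -> milk.
    ``subject_sd``/``resid_sd`` give random-intercept and residual SDs for
    the structural mediator and outcome; non-structural hormones use the
    marginal ``log_sd`` split evenly between subject and residual variance.
    """

    n_dyads: int = 223
    visit_windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(VISIT_BOUNDS)
    )
    hormone_medians: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MEDIANS.items()}
    )
    log_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LOG_SD))
    a1: float = 0.0
    b1: float = 0.0
    b3: float = 0.0
    c1_prime: float = 0.0
    mediation_hormone: str = "leptin"
    covariate_effects: dict[str, float] = field(default_factory=dict)
    subject_sd: dict[str, float] = field(
        default_factory=lambda: {"mediator": 0.5, "outcome": 0.6}
    )
    resid_sd: dict[str, float] = field(
        default_factory=lambda: {"mediator": 0.5, "outcome": 0.6}
    )
    exposure_dist: ExposureDist = field(default_factory=ExposureDist)
    infant_effects: InfantEffects = field(default_factory=InfantEffects)
    lod_censor: bool = True
    infant_blood_split: float = 0.5
    dropout: dict[str, float] = field(
        default_factory=lambda: {"V1": 0.65, "V2": 1.0, "V3": 0.94, "V4": 0.91}
    )
    feed_miss_rate: float = 0.01
    feed_spike_rate: float = 0.002
    birth_weight_mean_g: float = 3510.0
    birth_weight_sd_g: float = 364.0
    seed: int | None = None

    def validate(self) -> None:
        if self.n_dyads <= 0:
            raise ValueError("n_dyads must be positive")
        if self.seed is None:
            raise ValueError("a seed is required for reproducible generation")
        if not (0.0 <= self.infant_blood_split <= 1.0):
            raise ValueError("infant_blood_split must be in [0, 1]")
        for v in self.dropout.values():
            if not (0.0 <= v <= 1.0):
                raise ValueError("retention probabilities must be in [0, 1]")
        for d in (self.subject_sd, self.resid_sd):
            if any(s < 0 for s in d.values()):
                raise ValueError("standard deviations must be non-negative")
        if any(s < 0 for s in self.log_sd.values()):
            raise ValueError("log_sd values must be non-negative")
        for med in self.hormone_medians.values():
            if any(m <= 0 for m in med.values()):
                raise ValueError("hormone medians must be strictly positive")
        prev_hi = -np.inf
        for label in ("V2", "V3", "V4"):
            lo, hi = self.visit_windows[label]
            if not (prev_hi <= lo < hi):
                raise ValueError("visit windows must be increasing and non-overlapping")
            prev_hi = hi
        if self.mediation_hormone not in HORMONES:
            raise ValueError(f"unknown hormone {self.mediation_hormone!r}")


@dataclass
class CohortTruth:
    """Generating parameters plus realised latent state, for recovery tests."""

    a1: float
    b1: float
    b3: float
    c1_prime: float
    infant_effects: InfantEffects
    subject_sd: dict[str, float]
    resid_sd: dict[str, float]
    covariate_effects: dict[str, float]
    mediation_hormone: str
    seed: int
    random_intercepts: pd.DataFrame  # dyad_id, u_mediator, v_outcome
    latent: pd.DataFrame  # pre-censoring hormone values per dyad-visit

    def to_json(self) -> str:
        d = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name not in ("random_intercepts", "latent", "infant_effects")
        }
        d["infant_effects"] = dataclasses.asdict(self.infant_effects)
        d["random_intercepts"] = self.random_intercepts.to_dict(orient="list")
        d["latent"] = self.latent.to_dict(orient="list")
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "CohortTruth":
        d = json.loads(text)
        d["infant_effects"] = InfantEffects(**d["infant_effects"])
        d["random_intercepts"] = pd.DataFrame(d["random_intercepts"])
        d["latent"] = pd.DataFrame(d["latent"])
        return cls(**d)


def _truncnorm(rng, mean, sd, lo, hi, size):
    """Normal draws clipped into [lo, hi] by resampling (vectorised)."""
    x = rng.normal(mean, sd, size)
    bad = (x < lo) | (x > hi)
    while bad.any():
        x[bad] = rng.normal(mean, sd, bad.sum())
        bad = (x < lo) | (x > hi)
    return x


def generate_cohort(
    params: CohortParams,
) -> tuple[pd.DataFrame, list[FeedLog], CohortTruth]:
    """Generate a full synthetic cohort.

    Returns the dyad-visit table (one row per retained dyad-visit, V1-V4),
    the per-dyad-visit 24-h feed logs (V2-V4 only), and the generating truth.
    Below-LOD hormone values are blanked and flagged when ``lod_censor`` is
    on; the uncensored values live in ``truth.latent``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_dyads
    ed = params.exposure_dist
    med_h = params.mediation_hormone

    dyad_id = np.arange(n)
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    height = rng.normal(ed.height_mean_m, ed.height_sd_m, n)
    bmi_base = rng.normal(ed.bmi_mean, ed.bmi_sd, n)
    birth_weight = rng.normal(params.birth_weight_mean_g, params.birth_weight_sd_g, n)
    u_med = rng.normal(0.0, params.subject_sd["mediator"], n)
    v_out = rng.normal(0.0, params.subject_sd["outcome"], n)
    w_inf = rng.normal(0.0, 0.5, n)  # infant plasma subject intercept (log scale)
    growth_z = rng.normal(0.0, 1.0, n)  # shared infant-size intercept (z units)
    blood_v3 = rng.random(n) < params.infant_blood_split
    retained = {v: rng.random(n) < p for v, p in params.dropout.items()}

    lod_cfg = AssayConfig()
    rows: list[pd.DataFrame] = []
    latent_rows: list[pd.DataFrame] = []
    feed_specs: list[tuple[int, str, float]] = []  # dyad, visit, daily total

    # colostrum visit: milk hormones only
    keep1 = retained["V1"]
    if keep1.any():
        k = keep1.sum()
        age1 = rng.uniform(1.0, 3.0, k) / 30.4375  # 24-72 h in months
        row = {
            "dyad_id": dyad_id[keep1],
            "visit": "V1",
            "infant_age_months": age1,
            "infant_sex": sex[keep1],
            "birth_weight_g": birth_weight[keep1],
        }
        for h in HORMONES:
            col = f"milk_{h}"
            med = params.hormone_medians[col]["V1"]
            if h == med_h:
                vals = np.exp(
                    np.log(med) + v_out[keep1]
                    + rng.normal(0.0, params.resid_sd["outcome"], k)
                )
            else:
                s = params.log_sd[col] / np.sqrt(2.0)
                subj = rng.normal(0.0, s, n)
                vals = np.exp(np.log(med) + subj[keep1] + rng.normal(0.0, s, k))
            row[col] = vals
        rows.append(pd.DataFrame(row))
        latent_rows.append(pd.DataFrame(
            {"dyad_id": dyad_id[keep1], "visit": "V1",
             **{f"milk_{h}": row[f"milk_{h}"] for h in HORMONES}}
        ))

    # non-structural hormones share a per-subject intercept across visits
    subj_int = {
        col: rng.normal(0.0, params.log_sd[col] / np.sqrt(2.0), n)
        for col in DEFAULT_LOG_SD
    }

    for vi, visit in enumerate(("V2", "V3", "V4")):
        keep = retained[visit]
        k = keep.sum()
        if k == 0:
            continue
        ids = dyad_id[keep]
        mu_age, sd_age = VISIT_AGE[visit]
        lo, hi = params.visit_windows[visit]
        age = _truncnorm(rng, mu_age, sd_age, lo, hi, k)
        bmi = (
            bmi_base[keep]
            + ed.visit_drift * vi
            + rng.normal(0.0, ed.within_visit_sd, k)
        )
        xc = bmi - ed.bmi_mean
        fmi = ed.fmi_intercept + ed.fmi_slope * bmi + rng.normal(0.0, ed.fmi_sd, k)
        fmi = np.clip(fmi, 0.5, None)
        h_m = height[keep]
        weight = bmi * h_m**2
        fm = fmi * h_m**2
        ffm = np.clip(weight - fm, 1.0, None)

        row: dict[str, np.ndarray | str] = {
            "dyad_id": ids,
            "visit": visit,
            "infant_age_months": age,
            "infant_sex": sex[keep],
            "maternal_height_m": h_m,
            "maternal_weight_kg": weight,
            "maternal_bmi": bmi,
            "maternal_fm_kg": fm,
            "maternal_ffm_kg": ffm,
            "maternal_fmi": fmi,
            "maternal_ffmi": ffm / h_m**2,
            "birth_weight_g": birth_weight[keep],
        }

        # covariate effects on the structural outcome
        cov_shift = np.zeros(k)
        for key, beta in params.covariate_effects.items():
            if key == "sex_female":
                cov_shift += beta * (sex[keep] == "female")
            elif key == "centered_age":
                cov_shift += beta * (age - mu_age)
            else:
                raise ValueError(f"unsupported covariate effect {key!r}")

        # maternal plasma (mediator compartment) and milk (outcome)
        mc_struct = np.zeros(k)
        for h in HORMONES:
            pcol, mcol = f"plasma_{h}", f"milk_{h}"
            pmed = params.hormone_medians[pcol][visit]
            mmed = params.hormone_medians[mcol][visit]
            if h == med_h:
                mc = (
                    params.a1 * xc
                    + u_med[keep]
                    + rng.normal(0.0, params.resid_sd["mediator"], k)
                )
                log_m = np.log(pmed) + mc
                log_y = (
                    np.log(mmed)
                    + params.c1_prime * xc
                    + params.b1 * mc
                    + params.b3 * xc * mc
                    + cov_shift
                    + v_out[keep]
                    + rng.normal(0.0, params.resid_sd["outcome"], k)
                )
                row[pcol] = np.exp(log_m)
                row[mcol] = np.exp(log_y)
                mc_struct = np.log(row[mcol]) - np.log(mmed)
            else:
                for col, med in ((pcol, pmed), (mcol, mmed)):
                    s = params.log_sd[col] / np.sqrt(2.0)
                    row[col] = np.exp(
                        np.log(med) + subj_int[col][keep] + rng.normal(0.0, s, k)
                    )

        # infant plasma: all infants sampled at V2, half at V3, half at V4
        if visit == "V2":
            sampled = np.ones(k, dtype=bool)
        elif visit == "V3":
            sampled = blood_v3[keep]
        else:
            sampled = ~blood_v3[keep]
        ie = params.infant_effects
        for h in HORMONES:
            col = f"infant_plasma_{h}"
            med = params.hormone_medians[col][visit]
            if h == med_h:
                s = params.log_sd[col] / np.sqrt(2.0)
                log_ip = (
                    np.log(med) + ie.a1 * mc_struct + w_inf[keep]
                    + rng.normal(0.0, s, k)
                )
                vals = np.exp(log_ip)
                ipc = log_ip - np.log(med)
            else:
                s = params.log_sd[col] / np.sqrt(2.0)
                vals = np.exp(
                    np.log(med) + subj_int[col][keep] + rng.normal(0.0, s, k)
                )
            row[col] = np.where(sampled, vals, np.nan)

        # infant growth: visit/sex means + shared subject intercept + the
        # configured infant-side pathway acting on weight
        for (var, sx), (means, sd_v) in GROWTH.items():
            base = np.where(sex[keep] == sx, means[vi], 0.0)
            if var not in row:
                row[var] = np.zeros(k)
            row[var] = row[var] + base
        for var in ("infant_weight_g", "infant_length_cm", "infant_fmi", "infant_bodyfat_pct"):
            sd_v = GROWTH[(var, "male")][1]
            row[var] = (
                row[var]
                + 0.7 * sd_v * growth_z[keep]
                + rng.normal(0.0, 0.7 * sd_v, k)
            )
        # latent infant plasma drives weight even where blood was not drawn
        row["infant_weight_g"] = (
            row["infant_weight_g"]
            + ie.c1_prime * mc_struct
            + (ie.b1 + ie.b3 * mc_struct) * ipc
        )

        e_mu, e_sd = MILK_ENERGY[visit]
        row["milk_energy_kcal_l"] = rng.normal(e_mu, e_sd, k)

        df = pd.DataFrame(row)
        latent_rows.append(
            df[["dyad_id", "visit"]].assign(
                **{c: df[c] for c in HORMONE_COLUMNS if c in df}
            )
        )

        # LOD censoring in reporting units
        if params.lod_censor:
            for col, (hname, scale) in HORMONE_COLUMNS.items():
                if col not in df:
                    continue
                lod = lod_cfg.lod[hname] * scale
                vals = df[col].to_numpy(float)
                below = vals < lod
                df[col] = np.where(below, np.nan, vals)
                df[f"{col}_blod"] = below & ~np.isnan(vals)
        rows.append(df)

        # feed-log daily totals from visit/sex intake means
        totals = np.clip(
            np.where(
                sex[keep] == "male",
                INTAKE_MEANS["male"][vi],
                INTAKE_MEANS["female"][vi],
            )
            + rng.normal(0.0, INTAKE_SD, k),
            200.0,
            None,
        )
        feed_specs.extend(zip(ids.tolist(), [visit] * k, totals.tolist()))

    visit_table = pd.concat(rows, ignore_index=True, sort=False)
    order = ["dyad_id", "visit"]
    visit_table = visit_table.sort_values(order, kind="stable").reset_index(drop=True)

    feed_logs = []
    for dyad, visit, total in feed_specs:
        n_feeds = int(np.clip(rng.poisson(8), 4, 14))
        miss_k = int(rng.binomial(n_feeds, params.feed_miss_rate))
        spike_k = int(rng.binomial(n_feeds, params.feed_spike_rate))
        miss_k = min(miss_k, max(0, n_feeds - spike_k - 1))
        log = generate_feed_log(
            daily_total_ml=float(total),
            n_feeds=n_feeds,
            noise_sd=0.0,
            miss_k=miss_k,
            spike_k=spike_k,
            rng=rng,
            dyad_id=int(dyad),
            visit=str(visit),
        )
        feed_logs.append(log)

    truth = CohortTruth(
        a1=params.a1, b1=params.b1, b3=params.b3, c1_prime=params.c1_prime,
        infant_effects=params.infant_effects,
        subject_sd=dict(params.subject_sd), resid_sd=dict(params.resid_sd),
        covariate_effects=dict(params.covariate_effects),
        mediation_hormone=med_h, seed=int(params.seed),
        random_intercepts=pd.DataFrame(
            {"dyad_id": dyad_id, "u_mediator": u_med, "v_outcome": v_out}
        ),
        latent=pd.concat(latent_rows, ignore_index=True, sort=False),
    )
    return visit_table, feed_logs, truth


def generate_feed_log(
    daily_total_ml: float,
    n_feeds: int,
    noise_sd: float = 0.0,
    miss_k: int = 0,
    spike_k: int = 0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    dyad_id: int = 0,
    visit: str = "V2",
    base_weight_g: float = 5500.0,
) -> FeedLog:
    """One 24-h test-weighing protocol with known daily total.

    ``n_feeds`` timestamped feeds in a window starting 08:00; the pre/post
    weight differences sum exactly to ``daily_total_ml`` before any
    perturbation. ``noise_sd`` adds gram-scale weighing noise to each
    recorded weight; ``miss_k`` feeds then have one weight deleted and
    ``spike_k`` feeds have their difference forced above 400 g.
    """
    if daily_total_ml <= 0:
        raise ValueError("daily_total_ml must be positive")
    if n_feeds < 1:
        raise ValueError("n_feeds must be at least 1")
    if miss_k < 0 or spike_k < 0:
        raise ValueError("miss_k and spike_k must be non-negative")
    if miss_k + spike_k > n_feeds:
        raise ValueError("cannot perturb more feeds than exist")
    if rng is None:
        if seed is None:
            raise ValueError("a seed or generator is required")
        rng = np.random.default_rng(seed)

    start = pd.Timestamp("2021-06-01 08:00:00")
    offsets = np.sort(rng.uniform(0.0, 23.5, n_feeds))
    # per-feed shares: positive and summing to 1
    shares = rng.gamma(4.0, 1.0, n_feeds)
    shares /= shares.sum()
    volumes = daily_total_ml * shares

    perturb = rng.permutation(n_feeds)
    spiked = set(perturb[:spike_k].tolist())
    missed = set(perturb[spike_k:spike_k + miss_k].tolist())

    events = []
    weight = base_weight_g
    for i in range(n_feeds):
        pre = weight + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        post = weight + volumes[i] + (
            rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        )
        if i in spiked:
            post = pre + 401.0 + rng.uniform(0.0, 100.0)
        pre_w: float | None = pre
        post_w: float | None = post
        if i in missed:
            if rng.random() < 0.5:
                pre_w = None
            else:
                post_w = None
        events.append(
            FeedEvent(
                start_time=start + pd.Timedelta(hours=float(offsets[i])),
                pre_weight_g=pre_w,
                post_weight_g=post_w,
                breast=("left", "right")[int(rng.random() < 0.5)],
            )
        )
        weight += volumes[i] * 0.0  # infant weight drifts negligibly intra-day
    return FeedLog(dyad_id=dyad_id, visit=visit, events=events, window_start=start)


def write_cohort(
    visit_table: pd.DataFrame,
    feed_logs: list[FeedLog],
    truth: CohortTruth,
    out_dir,
) -> None:
    """Write the cohort as UTF-8 CSVs (empty cell = missing) plus truth JSON."""
    from pathlib import Path

    from .weighing import feed_logs_to_frame

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    visit_table.to_csv(out / "visits.csv", index=False)
    feed_logs_to_frame(feed_logs).to_csv(out / "feed_logs.csv", index=False)
    (out / "truth.json").write_text(truth.to_json(), encoding="utf-8")


def read_truth(path) -> CohortTruth:
    from pathlib import Path

    return CohortTruth.from_json(Path(path).read_text(encoding="utf-8"))
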