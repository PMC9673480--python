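"""Turn raw dyad-visit records into analysis-ready variables.

Covers assay detection-limit handling (half-LOD substitution for
non-detectable hormone concentrations), anthropometric indices (BMI, fat-mass
and fat-free-mass index), adiposity categorisation, milk energy from
macronutrients, per-visit mean-centred infant age, and mapping of postpartum
age to the cohort's visit windows.

Units are fixed per hormone and compartment at ingest and never converted
downstream: milk leptin and insulin in pg/mL, milk adiponectin in ng/mL,
maternal/infant plasma leptin in ng/mL, plasma insulin in pg/mL, plasma
adiponectin in ug/mL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AssayConfig",
    "AdiposityThresholds",
    "EnergyFactors",
    "VISIT_WINDOWS",
    "HORMONE_COLUMNS",
    "impute_below_lod",
    "substitute_below_lod_frame",
    "compute_indices",
    "categorize_adiposity",
    "compute_energy",
    "center_age",
    "assign_visit_window",
    "preprocess_visit_table",
]


@dataclass(frozen=True)
class AssayConfig:
    """Assay lower limits of detection, in each hormone's assay unit.

    Insulin and leptin limits are in pg/mL, adiponectin in ng/mL.
    Non-detectable values are replaced by ``substitution_factor * LOD``
    (half the lower cut-off by default).
    """

    lod: dict[str, float] = field(
        default_factory=lambda: {"insulin": 12.0, "leptin": 11.0, "adiponectin": 5.0}
    )
    substitution_factor: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.substitution_factor <= 1.0):
            raise ValueError("substitution_factor must be in (0, 1]")
        for name, v in self.lod.items():
            if v <= 0:
                raise ValueError(f"LOD for {name} must be positive")


@dataclass(frozen=True)
class AdiposityThresholds:
    """Cut-offs for adiposity groups.

    Overweight is BMI >= bmi_cut (closed bound); excessive fat mass is
    FMI strictly > fmi_cut, so an FMI exactly at the cut is 'normal'.
    """

    bmi_cut: float = 25.0
    fmi_cut: float = 9.0

    def __post_init__(self) -> None:
        if self.bmi_cut <= 0 or self.fmi_cut <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class EnergyFactors:
    """Atwater-style energy density of milk macronutrients (kcal/g)."""

    carbohydrate: float = 4.0
    protein: float = 4.0
    fat: float = 9.0

    def __post_init__(self) -> None:
        if min(self.carbohydrate, self.protein, self.fat) <= 0:
            raise ValueError("energy factors must be positive")


#: Postpartum visit windows in months: V1 is colostrum (24-72 h after birth),
#: V2-V4 are the three postpartum visits.
VISIT_WINDOWS: dict[str, tuple[float, float]] = {
    "V2": (1.0, 3.5),
    "V3": (3.5, 6.0),
    "V4": (6.0, 8.5),
}

#: hormone concentration column -> (hormone, scale from assay unit to the
#: column's reporting unit).  Plasma leptin is reported in ng/mL while the
#: leptin assay LOD is quoted in pg/mL, hence the 1e-3 scale, etc.
HORMONE_COLUMNS: dict[str, tuple[str, float]] = {
    "milk_leptin": ("leptin", 1.0),
    "milk_insulin": ("insulin", 1.0),
    "milk_adiponectin": ("adiponectin", 1.0),
    "plasma_leptin": ("leptin", 1e-3),
    "plasma_insulin": ("insulin", 1.0),
    "plasma_adiponectin": ("adiponectin", 1e-3),
    "infant_plasma_leptin": ("leptin", 1e-3),
    "infant_plasma_insulin": ("insulin", 1.0),
    "infant_plasma_adiponectin": ("adiponectin", 1e-3),
}


def impute_below_lod(
    value: float | None, hormone: str, cfg: AssayConfig | None = None
) -> tuple[float, bool]:
    """Substitute a non-detectable concentration with a fraction of the LOD.

    ``value`` is in the hormone's assay unit. A missing value (None/NaN) or a
    value below the detection limit is treated as non-detectable and replaced
    by ``substitution_factor * LOD``; detectable values (>= LOD) pass through
    unchanged. Returns ``(concentration, below_lod_flag)``.

    The operation is idempotent: the substituted value is itself below the
    LOD and maps to the same substituted value on re-application.
    """
    cfg = cfg or AssayConfig()
    if hormone not in cfg.lod:
        raise KeyError(f"no LOD configured for hormone {hormone!r}")
    lod = cfg.lod[hormone]
    if value is not None and not (isinstance(value, float) and math.isnan(value)):
        if value < 0:
            raise ValueError("hormone concentration cannot be negative")
        if value >= lod:
            return float(value), False
    return cfg.substitution_factor * lod, True


def substitute_below_lod_frame(
    table: pd.DataFrame, cfg: AssayConfig | None = None
) -> pd.DataFrame:
    """Apply half-LOD substitution to every hormone column of a visit table.

    Missing concentrations are treated as non-detectable only when the
    corresponding ``*_blod`` flag column marks them as censored (an absent
    sample is not a censored one); flag columns are created when missing.
    """
    cfg = cfg or AssayConfig()
    out = table.copy()
    for col, (hormone, scale) in HORMONE_COLUMNS.items():
        if col not in out.columns:
            continue
        lod_col = lod_in_column_units(hormone, cfg) * _unit_scale(col)
        sub = cfg.substitution_factor * lod_col
        flag_col = f"{col}_blod"
        if flag_col in out.columns:
            censored = out[flag_col].map(lambda v: bool(v) if pd.notna(v) else False)
        else:
            censored = pd.Series(False, index=out.index)
        vals = out[col].astype(float)
        # a censored assay reports "non-detectable", not a numeric below the
        # LOD; unflagged missing values are absent samples and stay missing
        mask = censored | (vals.isna() & censored)
        out[col] = vals.mask(mask, sub)
        out[flag_col] = mask
    return out


def lod_in_column_units(hormone: str, cfg: AssayConfig | None = None) -> float:
    cfg = cfg or AssayConfig()
    return cfg.lod[hormone]


def _unit_scale(column: str) -> float:
    return HORMONE_COLUMNS[column][1]


def compute_indices(
    weight_kg: float,
    height_m: float,
    fm_kg: float | None = None,
    ffm_kg: float | None = None,
) -> tuple[float, float | None, float | None]:
    """BMI, fat-mass index and fat-free-mass index (all kg/m^2).

    Each index is the corresponding mass divided by squared height.
    FMI/FFMI are None when the mass is not supplied.
    """
    if height_m <= 0:
        raise ValueError("height must be positive")
    if weight_kg < 0 or (fm_kg is not None and fm_kg < 0) or (
        ffm_kg is not None and ffm_kg < 0
    ):
        raise ValueError("masses cannot be negative")
    h2 = height_m**2
    bmi = weight_kg / h2
    fmi = fm_kg / h2 if fm_kg is not None else None
    ffmi = ffm_kg / h2 if ffm_kg is not None else None
    return bmi, fmi, ffmi


def categorize_adiposity(
    bmi: float, fmi: float, th: AdiposityThresholds | None = None
) -> tuple[str, str]:
    """Classify maternal adiposity from BMI and FMI.

    BMI >= 25 kg/m^2 is 'overweight'; FMI > 9 is 'excessive' (exactly 9 is
    'normal' — the FMI bound is open, the BMI bound closed).
    """
    th = th or AdiposityThresholds()
    if bmi < 0 or fmi < 0:
        raise ValueError("indices cannot be negative")
    bmi_group = "overweight" if bmi >= th.bmi_cut else "normal"
    fmi_group = "excessive" if fmi > th.fmi_cut else "normal"
    return bmi_group, fmi_group


def compute_energy(
    fat_g_per_l: float,
    protein_g_per_l: float,
    carb_g_per_l: float,
    ef: EnergyFactors | None = None,
) -> float:
    """Milk energy concentration (kcal/L) from macronutrient concentrations."""
    ef = ef or EnergyFactors()
    if min(fat_g_per_l, protein_g_per_l, carb_g_per_l) < 0:
        raise ValueError("macronutrient concentrations cannot be negative")
    return ef.fat * fat_g_per_l + ef.protein * protein_g_per_l + ef.carbohydrate * carb_g_per_l


def center_age(
    visit_table: pd.DataFrame,
    age_col: str = "infant_age_months",
    visit_col: str = "visit",
) -> pd.DataFrame:
    """Add a ``centered_age`` column: age minus the mean age at that visit.

    The per-visit mean of the centred age is zero by construction. Sign
    convention: a positive centred age means the infant was older than
    average at the visit.
    """
    if visit_table.empty:
        raise ValueError("cannot centre age on an empty table")
    out = visit_table.copy()
    out["centered_age"] = out[age_col] - out.groupby(visit_col)[age_col].transform("mean")
    return out


def assign_visit_window(postpartum_months: float) -> str:
    """Map postpartum age (months) to a visit label.

    Colostrum collection (within 72 h of birth) is V1; the postpartum visit
    windows are 1.0-3.49 (V2), 3.5-5.99 (V3) and 6.0-8.5 (V4) months, treated
    half-open at the interior boundaries. Ages outside every window map to
    'unassigned'.
    """
    if postpartum_months < 0:
        raise ValueError("postpartum age cannot be negative")
    if postpartum_months * 730.5 <= 72.0:  # hours, using the mean month length
        return "V1"
    for label, (lo, hi) in VISIT_WINDOWS.items():
        if label == "V4":
            if lo <= postpartum_months <= hi:
                return label
        elif lo <= postpartum_months < hi:
            return label
    return "unassigned"


def preprocess_visit_table(
    table: pd.DataFrame,
    assay: AssayConfig | None = None,
    thresholds: AdiposityThresholds | None = None,
) -> pd.DataFrame:
    """Full preprocessing pass over a raw visit table.

    Applies half-LOD substitution, adds log-scale hormone columns, adiposity
    groups and per-visit centred age. Rows at V1 (colostrum) have no
    anthropometry and keep missing group labels.
    """
    th = thresholds or AdiposityThresholds()
    out = substitute_below_lod_frame(table, assay)
    for col in HORMONE_COLUMNS:
        if col in out.columns:
            out[f"log_{col}"] = np.log(out[col].astype(float))
    if {"maternal_bmi", "maternal_fmi"} <= set(out.columns):
        bmi = out["maternal_bmi"].astype(float)
        fmi = out["maternal_fmi"].astype(float)
        out["bmi_group"] = np.where(bmi.isna(), None, np.where(bmi >= th.bmi_cut, "overweight", "normal"))
        out["fmi_group"] = np.where(fmi.isna(), None, np.where(fmi > th.fmi_cut, "excessive", "normal"))
        out["bmi_overweight"] = (bmi >= th.bmi_cut).astype(float).mask(bmi.isna())
        out["fmi_excessive"] = (fmi > th.fmi_cut).astype(float).mask(fmi.isna())
    if {"infant_age_months", "visit"} <= set(out.columns):
        out = center_age(out)
    return out
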