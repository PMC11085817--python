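"""Phenotype and lifestyle tables.

Raw per-participant data: height (cm), weight (kg), age (years), sex, type-2
diabetes status, weekly physical-activity minutes, eating-habits Likert item
responses, sugar-sweetened-beverage cups/day, and wine drinks/week (possibly
missing).  BMI is derived as weight / (height/100)^2 and obesity as
BMI >= 30 kg/m^2; the eating-habits score (EHS) is the item sum.

Lifestyle exposure flags use boundary-inclusive thresholds:

- active:        pa_min_week >= 90
- ehs_high:      ehs_score >= cohort median (median over all scored
                 participants, linear interpolation)
- ssb_consumer:  ssb_cups_day >= 1
- wine_moderate: 1 <= wine_drinks_week <= 3 (missing propagated)

Sex is coded female = 1, male = 0 in every model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

OBESITY_BMI_THRESHOLD = 30.0
PA_ACTIVE_MIN_PER_WEEK = 90.0
SSB_CONSUMER_CUPS_PER_DAY = 1.0
WINE_MODERATE_RANGE = (1.0, 3.0)

_REQUIRED = ["id", "height_cm", "weight_kg", "age", "sex", "t2dm",
             "pa_min_week", "ssb_cups_day", "wine_drinks_week"]


def _coerce_sex(values: pd.Series) -> pd.Series:
    """Map sex to female=1 / male=0, accepting strings or 0/1 integers."""
    if values.dtype == object:
        mapping = {"female": 1, "f": 1, "male": 0, "m": 0}
        out = values.astype(str).str.strip().str.lower().map(mapping)
        if out.isna().any():
            bad = values[out.isna()].unique().tolist()
            raise InputError(f"unrecognised sex values: {bad}")
        return out.astype(int)
    out = pd.to_numeric(values)
    if not out.isin([0, 1]).all():
        raise InputError("numeric sex must be 0 (male) or 1 (female)")
    return out.astype(int)


@dataclass
class PhenotypeTable:
    """Validated phenotype table with derived BMI, obesity and EHS columns.

    ``data`` holds one row per participant with at least the raw columns
    listed in the module docstring plus zero or more ``ehs_item_*`` Likert
    columns; construction adds ``sex_female``, ``bmi``, ``obesity`` and
    ``ehs_score``.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        d = self.data.copy().reset_index(drop=True)
        missing = [c for c in _REQUIRED if c not in d.columns]
        if missing:
            raise InputError(f"phenotype table missing columns: {missing}")
        if d["id"].duplicated().any():
            raise InputError("duplicate participant ids")
        d["id"] = d["id"].astype(str)
        d["sex_female"] = _coerce_sex(d["sex"])
        for col in ("height_cm", "weight_kg", "age"):
            if (pd.to_numeric(d[col]) <= 0).any():
                raise InputError(f"non-positive values in {col}")
        for col in ("pa_min_week", "ssb_cups_day"):
            if (pd.to_numeric(d[col]) < 0).any():
                raise InputError(f"negative values in {col}")
        wine = pd.to_numeric(d["wine_drinks_week"])
        if (wine.dropna() < 0).any():
            raise InputError("negative values in wine_drinks_week")
        d["t2dm"] = pd.to_numeric(d["t2dm"]).astype(int)
        d["bmi"] = d["weight_kg"] / (d["height_cm"] / 100.0) ** 2
        d["obesity"] = (d["bmi"] >= OBESITY_BMI_THRESHOLD).astype(int)
        item_cols = self.ehs_item_columns(d)
        if item_cols:
            d["ehs_score"] = d[item_cols].sum(axis=1)
        elif "ehs_score" not in d.columns:
            raise InputError("need ehs_item_* columns or an ehs_score column")
        self.data = d

    @staticmethod
    def ehs_item_columns(frame: pd.DataFrame) -> list[str]:
        return [c for c in frame.columns if c.startswith("ehs_item_")]

    @classmethod
    def from_csv(cls, path) -> "PhenotypeTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        raw = [c for c in self.data.columns
               if c not in ("sex_female", "bmi", "obesity", "ehs_score")]
        out = self.data[raw].copy()
        out.to_csv(path, index=False, float_format="%.6g")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def ids(self) -> list[str]:
        return self.data["id"].tolist()

    def ehs_median(self) -> float:
        """Cohort EHS median (linear interpolation) over scored participants."""
        scores = self.data["ehs_score"].dropna()
        if scores.empty:
            raise InputError("no EHS scores available")
        return float(np.median(scores))


def derive_flags(phenotypes: PhenotypeTable) -> pd.DataFrame:
    """Derive lifestyle exposure flags (one row per participant).

    Returns a DataFrame indexed like the phenotype table with integer columns
    ``active``, ``ehs_high``, ``ssb_consumer``, ``wine_moderate`` and
    ``wine_missing``.  ``wine_moderate`` is NaN where wine intake is missing.
    All thresholds are boundary-inclusive; the EHS cutoff is the cohort
    median of all scored participants, so the flag depends on the cohort,
    not only on the row.
    """
    d = phenotypes.data
    med = phenotypes.ehs_median()
    wine = pd.to_numeric(d["wine_drinks_week"])
    lo, hi = WINE_MODERATE_RANGE
    flags = pd.DataFrame({
        "id": d["id"],
        "active": (d["pa_min_week"] >= PA_ACTIVE_MIN_PER_WEEK).astype(int),
        "ehs_high": (d["ehs_score"] >= med).astype(int),
        "ssb_consumer": (d["ssb_cups_day"] >= SSB_CONSUMER_CUPS_PER_DAY).astype(int),
        "wine_moderate": ((wine >= lo) & (wine <= hi)).astype(float).where(wine.notna()),
        "wine_missing": wine.isna().astype(int),
    })
    return flags
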