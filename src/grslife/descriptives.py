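"""Cohort descriptive statistics split by obesity status.

Produces the classic baseline table: continuous variables as mean +/- SD
with an independent two-sided t-test, skewed variables as median (IQR) with
a Mann-Whitney U test, categorical variables as n (%) with a chi-square
test.  Which variable gets which test is declared in a mapping (and echoed
in the output), not inferred from the data.

Percentages are always recomputed as 100 * count / denominator (rounded to
2 decimals in reports); the denominator is the group size, except that wine
consumption can optionally use complete cases only (excluding participants
with missing wine data) — the default keeps the full group denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

DEFAULT_TEST_MAP = {
    "age": "t",
    "height_cm": "t",
    "weight_kg": "t",
    "bmi": "t",
    "ehs_score": "mann_whitney",
    "sex_female": "chi_square",
    "t2dm": "chi_square",
    "active": "chi_square",
    "ssb_consumer": "chi_square",
    "wine_moderate": "chi_square",
}

DISPLAY_NAMES = {
    "age": "Age (years)",
    "height_cm": "Height (cm)",
    "weight_kg": "Weight (kg)",
    "bmi": "BMI (kg/m^2)",
    "ehs_score": "EHS score",
    "sex_female": "Sex (female)",
    "t2dm": "T2DM (n, %)",
    "active": "PA >= 90 (n, %)",
    "ssb_consumer": "SSB consumers (n, %)",
    "wine_moderate": "Wine consumers (n, %)",
}


def percentage(count: int, denominator: int, decimals: int = 2) -> float:
    """100 * count / denominator, rounded; the only way reports compute %."""
    if denominator <= 0:
        raise InputError("percentage denominator must be positive")
    return round(100.0 * count / denominator, decimals)


@dataclass
class DescriptiveRow:
    variable: str
    overall: str
    obese: str
    non_obese: str
    test: str
    p: float


def _continuous_cell(values: np.ndarray) -> str:
    return f"{np.mean(values):.2f} ± {np.std(values, ddof=1):.2f}"


def _median_cell(values: np.ndarray) -> str:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return f"{med:.2f} ({q1:.2f}-{q3:.2f})"


def _count_cell(flag: pd.Series, denominator: int) -> str:
    count = int(flag.sum())
    return f"{count} ({percentage(count, denominator):.2f})"


def describe_cohort(
    frame: pd.DataFrame,
    test_map: dict[str, str] | None = None,
    wine_complete_case_denominator: bool = False,
) -> pd.DataFrame:
    """Baseline descriptive table split by obesity status.

    ``frame`` must carry ``obesity`` plus the variables in ``test_map``
    (default :data:`DEFAULT_TEST_MAP`); flag variables are 0/1 (wine may be
    NaN = missing).  Returns one row per variable with overall / obese /
    non-obese summaries, the test used and its two-sided p-value.
    """
    test_map = dict(test_map or DEFAULT_TEST_MAP)
    groups = {
        "obese": frame[frame["obesity"] == 1],
        "non_obese": frame[frame["obesity"] == 0],
    }
    if any(len(g) == 0 for g in groups.values()):
        raise InputError("empty obesity group: cannot describe the split")

    rows = []
    for var, test in test_map.items():
        if var not in frame.columns:
            continue
        cells = {}
        if test in ("t", "mann_whitney"):
            parts = {name: g[var].dropna().to_numpy(dtype=float)
                     for name, g in {"overall": frame, **groups}.items()}
            fmt = _continuous_cell if test == "t" else _median_cell
            cells = {name: fmt(v) for name, v in parts.items()}
            if test == "t":
                _, p = stats.ttest_ind(parts["obese"], parts["non_obese"], equal_var=False)
            else:
                _, p = stats.mannwhitneyu(parts["obese"], parts["non_obese"],
                                          alternative="two-sided")
        elif test == "chi_square":
            col = frame[var]
            complete_only = wine_complete_case_denominator and var == "wine_moderate"
            for name, g in {"overall": frame, **groups}.items():
                flag = g[var]
                denom = int(flag.notna().sum()) if complete_only else len(g)
                cells[name] = _count_cell(flag.fillna(0), denom)
            tab = pd.crosstab(col.dropna(), frame.loc[col.notna(), "obesity"])
            _, p, _, _ = stats.chi2_contingency(tab)
        else:
            raise InputError(f"unknown test {test!r} for variable {var!r}")
        rows.append(DescriptiveRow(
            variable=DISPLAY_NAMES.get(var, var),
            overall=cells["overall"], obese=cells["obese"],
            non_obese=cells["non_obese"], test=test, p=float(p)))
    out = pd.DataFrame([r.__dict__ for r in rows])
    return out
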