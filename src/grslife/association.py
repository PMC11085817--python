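"""Association models and stratified contrasts.

Fits the analysis battery relating the weighted risk score to obesity and
BMI, and the gene-lifestyle interplay contrasts:

- logistic regression of obesity on the continuous score, adjusted for age,
  sex and T2DM (odds ratio per score unit, Wald 95% CI);
- OLS of BMI on the score (slope in kg/m^2 per score unit, R^2);
- logistic obesity on quartile indicators (Q1 reference) with the same
  covariates;
- within each score quartile, the exposed-vs-unexposed obesity OR (adjusted)
  and the crude BMI difference with a Welch 95% CI, for each lifestyle
  exposure;
- all 6 pairwise quartile mean-BMI contrasts (optionally inside one exposure
  stratum) via two-sided Welch t-tests with Bonferroni adjustment over the
  family of 6.

Conventions: Wald confidence intervals on the log-odds / slope scale, 95%
fixed; complete-case analysis per model (only wine analyses drop the
wine-missing participants); maximum likelihood via IRLS with tolerance 1e-8
and at most 100 iterations, with separation reported as an explicit fit
failure, never silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import FitError, InputError
from .grs import QUARTILE_LABELS, GRSResult
from .phenotypes import PhenotypeTable, derive_flags

ADJUST_COVARIATES = ("age", "sex_female", "t2dm")
BONFERRONI_FAMILY = 6  # pairwise contrasts among 4 quartiles

EXPOSURES = {
    # analysis name -> (flag column, exposed label, unexposed label)
    "pa": ("active", "active", "inactive"),
    "ehs": ("ehs_high", "EHS>=median", "EHS<median"),
    "ssb": ("ssb_consumer", "SSB consumer", "non-consumer"),
    "wine": ("wine_moderate", "moderate drinker", "non-drinker"),
}


@dataclass
class EffectEstimate:
    """A single regression effect: OR or slope with Wald 95% CI and p."""

    effect_type: str  # "odds_ratio" | "slope"
    point: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    covariates: tuple = ()
    r_squared: float | None = None
    term: str = ""

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.point <= self.ci_high):
            raise FitError(f"CI does not bracket the point estimate for {self.term}")


@dataclass
class StratumComparison:
    """Exposure contrast inside one score quartile."""

    quartile: str
    exposure: str
    n_exposed: int
    n_unexposed: int
    mean_exposed: float
    sd_exposed: float
    mean_unexposed: float
    sd_unexposed: float
    diff: float
    diff_ci: tuple
    diff_p: float
    or_within: EffectEstimate | None  # None when not estimable
    note: str = ""


@dataclass
class ComparisonSet:
    """A Bonferroni family of pairwise quartile mean contrasts."""

    stratum: str
    contrasts: pd.DataFrame = field(repr=False)  # one row per pair
    m: int = BONFERRONI_FAMILY


def bonferroni(p_raw: np.ndarray, m: int) -> np.ndarray:
    """adjusted_p = min(1, m * raw_p), elementwise."""
    return np.minimum(1.0, m * np.asarray(p_raw, dtype=float))


def welch_ci(x: np.ndarray, y: np.ndarray, alpha: float = 0.05):
    """Welch two-sample difference in means: (diff, lo, hi, p).

    diff = mean(x) - mean(y); CI and two-sided p use the Welch-Satterthwaite
    degrees of freedom.  Requires n >= 2 per group.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InputError("Welch comparison needs at least 2 observations per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    diff = x.mean() - y.mean()
    if se2 == 0:
        return diff, diff, diff, 1.0
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    se = np.sqrt(se2)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    t = diff / se
    p = 2 * stats.t.sf(abs(t), df)
    return float(diff), float(diff - tcrit * se), float(diff + tcrit * se), float(p)


def _fit_logit(y: np.ndarray, X: np.ndarray) -> sm.discrete.discrete_model.BinaryResults:
    """ML logistic fit with explicit failure on non-convergence/separation."""
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=100, tol=1e-8)
    except Exception as exc:
        raise FitError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise FitError("logistic fit did not converge")
    if not np.all(np.isfinite(fit.bse)) or np.any(np.abs(fit.params) > 15):
        raise FitError("separation suspected: unbounded coefficient")
    return fit


def _logit_effect(frame: pd.DataFrame, term: str, adjust: bool = True) -> EffectEstimate:
    """Adjusted logistic OR for ``term`` from a complete-case frame with an
    ``obesity`` column."""
    cols = [term] + (list(ADJUST_COVARIATES) if adjust else [])
    data = frame[["obesity"] + cols].dropna()
    y = data["obesity"].to_numpy(dtype=float)
    X = sm.add_constant(data[cols].to_numpy(dtype=float), has_constant="add")
    fit = _fit_logit(y, X)
    coef, bse = fit.params[1], fit.bse[1]
    z = stats.norm.ppf(0.975)
    return EffectEstimate(
        effect_type="odds_ratio",
        point=float(np.exp(coef)),
        ci_low=float(np.exp(coef - z * bse)),
        ci_high=float(np.exp(coef + z * bse)),
        p=float(fit.pvalues[1]),
        n=len(data),
        covariates=tuple(ADJUST_COVARIATES) if adjust else (),
        term=term,
    )


def build_analysis_frame(scores: GRSResult, phenotypes: PhenotypeTable) -> pd.DataFrame:
    """Merge scores, phenotypes and derived lifestyle flags on participant id.

    Only scored participants are kept (the missing-genotype policy has
    already dropped the rest); quartile labels, if assigned, come along.
    """
    flags = derive_flags(phenotypes)
    pheno = phenotypes.data.merge(flags.drop(columns="id"), left_index=True, right_index=True)
    merged = scores.scores.join(pheno.set_index("id"), how="inner")
    if len(merged) != len(scores.scores):
        missing = set(scores.scores.index) - set(pheno["id"])
        raise InputError(f"phenotypes missing for scored participants: {sorted(missing)[:5]}")
    return merged


def fit_obesity_logistic(scores: GRSResult, phenotypes: PhenotypeTable) -> EffectEstimate:
    """Obesity ~ GRS + age + sex + T2DM; OR per score unit with Wald 95% CI."""
    frame = build_analysis_frame(scores, phenotypes)
    return _logit_effect(frame, "grs")


def fit_bmi_linear(scores: GRSResult, phenotypes: PhenotypeTable) -> EffectEstimate:
    """OLS of BMI on the score: slope (kg/m^2 per score unit), 95% CI, R^2."""
    frame = build_analysis_frame(scores, phenotypes)[["bmi", "grs"]].dropna()
    if frame["grs"].nunique() < 2:
        raise FitError("zero score variance: BMI slope undefined")
    X = sm.add_constant(frame["grs"].to_numpy(dtype=float))
    fit = sm.OLS(frame["bmi"].to_numpy(dtype=float), X).fit()
    lo, hi = fit.conf_int()[1]
    return EffectEstimate(
        effect_type="slope",
        point=float(fit.params[1]),
        ci_low=float(lo),
        ci_high=float(hi),
        p=float(fit.pvalues[1]),
        n=int(fit.nobs),
        r_squared=float(fit.rsquared),
        term="grs",
    )


def _quartile_pairs() -> list[tuple[str, str]]:
    labels = list(QUARTILE_LABELS)
    return [(labels[j], labels[i]) for i in range(4) for j in range(i + 1, 4)]


def quartile_bmi_contrasts(
    scores: GRSResult,
    phenotypes: PhenotypeTable,
    stratum: tuple | None = None,
) -> ComparisonSet:
    """All 6 pairwise quartile mean-BMI contrasts, Bonferroni-adjusted (m=6).

    ``stratum`` optionally restricts to one exposure level first, e.g.
    ``("pa", 0)`` for inactive participants; quartile labels stay as assigned
    on the full cohort.  Cells with n < 2 yield a not-estimable contrast row
    (NaN statistics, note set).
    """
    frame = build_analysis_frame(scores, phenotypes)
    label = "all"
    if stratum is not None:
        exposure, level = stratum
        flag, exposed_name, unexposed_name = EXPOSURES[exposure]
        frame = frame[frame[flag] == level]
        label = f"{exposure}={exposed_name if level else unexposed_name}"
    groups = {q: frame.loc[frame["quartile"] == q, "bmi"].to_numpy() for q in QUARTILE_LABELS}

    rows = []
    for hi, lo in _quartile_pairs():
        a, b = groups[hi], groups[lo]
        row = {"pair": f"{hi} vs {lo}", "n_a": len(a), "n_b": len(b),
               "mean_a": np.nan, "sd_a": np.nan, "mean_b": np.nan, "sd_b": np.nan,
               "diff": np.nan, "ci_low": np.nan, "ci_high": np.nan,
               "p_raw": np.nan, "note": ""}
        if len(a) < 2 or len(b) < 2:
            row["note"] = "not estimable: cell n < 2"
        else:
            diff, ci_lo, ci_hi, p = welch_ci(a, b)
            row.update(mean_a=a.mean(), sd_a=a.std(ddof=1),
                       mean_b=b.mean(), sd_b=b.std(ddof=1),
                       diff=diff, ci_low=ci_lo, ci_high=ci_hi, p_raw=p)
        rows.append(row)
    table = pd.DataFrame(rows)
    table["p_bonferroni"] = bonferroni(table["p_raw"].to_numpy(), BONFERRONI_FAMILY)
    return ComparisonSet(stratum=label, contrasts=table, m=BONFERRONI_FAMILY)


def within_quartile_exposure_effect(
    scores: GRSResult,
    phenotypes: PhenotypeTable,
    exposure: str,
) -> list[StratumComparison]:
    """Per quartile: exposed-vs-unexposed obesity OR and crude BMI contrast.

    The OR is adjusted for age, sex and T2DM; BMI means, SDs and the Welch
    difference are crude.  Wine analyses drop wine-missing participants;
    other exposures use all scored participants.  An empty or degenerate
    exposure cell yields a not-estimable entry rather than an exception.
    """
    if exposure not in EXPOSURES:
        raise InputError(f"unknown exposure {exposure!r}; one of {sorted(EXPOSURES)}")
    flag, _, _ = EXPOSURES[exposure]
    frame = build_analysis_frame(scores, phenotypes)
    frame = frame.dropna(subset=[flag])

    out = []
    for q in QUARTILE_LABELS:
        sub = frame[frame["quartile"] == q]
        exp_bmi = sub.loc[sub[flag] == 1, "bmi"].to_numpy()
        unexp_bmi = sub.loc[sub[flag] == 0, "bmi"].to_numpy()
        note = ""
        if len(exp_bmi) < 2 or len(unexp_bmi) < 2:
            out.append(StratumComparison(
                quartile=q, exposure=exposure,
                n_exposed=len(exp_bmi), n_unexposed=len(unexp_bmi),
                mean_exposed=np.nan, sd_exposed=np.nan,
                mean_unexposed=np.nan, sd_unexposed=np.nan,
                diff=np.nan, diff_ci=(np.nan, np.nan), diff_p=np.nan,
                or_within=None, note="not estimable: empty exposure cell"))
            continue
        diff, lo, hi, p = welch_ci(exp_bmi, unexp_bmi)
        try:
            or_within = _logit_effect(sub.assign(_exp=sub[flag].astype(float)), "_exp")
        except FitError as exc:
            or_within, note = None, f"OR not estimable: {exc}"
        out.append(StratumComparison(
            quartile=q, exposure=exposure,
            n_exposed=len(exp_bmi), n_unexposed=len(unexp_bmi),
            mean_exposed=float(exp_bmi.mean()), sd_exposed=float(exp_bmi.std(ddof=1)),
            mean_unexposed=float(unexp_bmi.mean()), sd_unexposed=float(unexp_bmi.std(ddof=1)),
            diff=diff, diff_ci=(lo, hi), diff_p=p, or_within=or_within, note=note))
    return out


def grs_quartile_obesity_trend(
    scores: GRSResult, phenotypes: PhenotypeTable
) -> dict[str, EffectEstimate]:
    """Obesity ~ quartile indicators (Q1 reference) + age + sex + T2DM.

    Returns ORs for Q2, Q3, Q4 vs Q1.  Raises :class:`FitError` when only the
    reference quartile is populated.
    """
    frame = build_analysis_frame(scores, phenotypes)
    present = [q for q in QUARTILE_LABELS if (frame["quartile"] == q).any()]
    if present == ["Q1"] or len(present) < 2:
        raise FitError("only the reference quartile is populated")
    dummies = pd.get_dummies(frame["quartile"]).reindex(columns=list(QUARTILE_LABELS), fill_value=0)
    cols = [q for q in ("Q2", "Q3", "Q4") if q in present]
    X = sm.add_constant(
        np.column_stack([dummies[cols].to_numpy(dtype=float),
                         frame[list(ADJUST_COVARIATES)].to_numpy(dtype=float)]),
        has_constant="add",
    )
    y = frame["obesity"].to_numpy(dtype=float)
    fit = _fit_logit(y, X)
    z = stats.norm.ppf(0.975)
    out = {}
    for i, q in enumerate(cols, start=1):
        coef, bse = fit.params[i], fit.bse[i]
        out[q] = EffectEstimate(
            effect_type="odds_ratio",
            point=float(np.exp(coef)),
            ci_low=float(np.exp(coef - z * bse)),
            ci_high=float(np.exp(coef + z * bse)),
            p=float(fit.pvalues[i]),
            n=len(frame),
            covariates=tuple(ADJUST_COVARIATES),
            term=f"{q} vs Q1",
        )
    return out
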