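"""SNP panel quality control and selection.

Implements the variant-selection pipeline applied before risk-score
construction:

1. minor-allele-frequency filter (strictly MAF > 0.01),
2. call-rate filter (default >= 0.95; "significant missing data" excluded),
3. per-SNP covariate-adjusted logistic screen — obesity ~ dosage + age +
   sex + T2DM, retaining SNPs with Wald p strictly < 0.05,
4. LD pruning: greedy tag-SNP selection keeping a SNP iff its composite
   genotypic r^2 (squared Pearson correlation of dosages,
   pairwise-complete) with every already-kept SNP is strictly < 0.8.

Pruning visits SNPs in a deterministic priority order: ascending screen
p-value, ties broken by descending MAF, then lexicographic rsid — so each
LD cluster is represented by its most informative member.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import FitError, InputError
from .genotypes import GenotypeMatrix
from .phenotypes import PhenotypeTable

MAF_MIN = 0.01
CALL_RATE_MIN = 0.95
LD_R2_MAX = 0.8
SCREEN_ALPHA = 0.05


@dataclass
class QCMetrics:
    """Per-SNP QC measures plus the pairwise dosage r^2 matrix.

    ``per_snp`` columns: ``maf``, ``effect_allele_freq``, ``call_rate`` and,
    once screening has run, ``screen_p`` (NaN = unscreenable).  ``r2`` is a
    symmetric DataFrame with unit diagonal; NaN marks pairs involving a
    zero-variance SNP.
    """

    per_snp: pd.DataFrame = field(repr=False)
    r2: pd.DataFrame | None = field(default=None, repr=False)


def compute_maf(genotypes: GenotypeMatrix) -> QCMetrics:
    """Effect-allele frequency, MAF and call rate per SNP.

    The effect-allele frequency is mean(dosage)/2 over non-missing calls and
    MAF = min(f, 1 - f).  A SNP with no non-missing calls gets NaN MAF and is
    flagged ``all_missing``.
    """
    d = genotypes.dosage
    n_obs = (~np.isnan(d)).sum(axis=0)
    sums = np.nansum(d, axis=0)
    freq = np.where(n_obs > 0, sums / np.maximum(n_obs, 1) / 2.0, np.nan)
    maf = np.minimum(freq, 1.0 - freq)
    per_snp = pd.DataFrame(
        {
            "effect_allele_freq": freq,
            "maf": maf,
            "call_rate": n_obs / max(genotypes.n_participants, 1),
            "all_missing": n_obs == 0,
        },
        index=genotypes.rsids,
    )
    return QCMetrics(per_snp=per_snp)


def filter_snps(
    metrics: QCMetrics,
    maf_min: float = MAF_MIN,
    call_rate_min: float = CALL_RATE_MIN,
) -> tuple[list[str], pd.DataFrame]:
    """Apply MAF (> maf_min, strict) and call-rate (>= call_rate_min) filters.

    Returns the retained rsid list (input order) and an exclusion log with a
    reason per excluded SNP.  An empty retained set is permitted.
    """
    rows = []
    retained = []
    for rsid, row in metrics.per_snp.iterrows():
        reasons = []
        if row["all_missing"]:
            reasons.append("all calls missing")
        else:
            if not row["maf"] > maf_min:
                reasons.append(f"maf {row['maf']:.4f} <= {maf_min}")
            if row["call_rate"] < call_rate_min:
                reasons.append(f"call_rate {row['call_rate']:.4f} < {call_rate_min}")
        if reasons:
            rows.append({"rsid": rsid, "reason": "; ".join(reasons)})
        else:
            retained.append(rsid)
    return retained, pd.DataFrame(rows, columns=["rsid", "reason"])


def pairwise_r2(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Composite genotypic LD: squared Pearson correlation of dosage vectors.

    Uses pairwise-complete observations.  Symmetric with unit diagonal; pairs
    involving a zero-variance SNP are NaN.
    """
    if genotypes.n_snps < 2:
        raise InputError("need at least two SNPs for pairwise r^2")
    m = genotypes.n_snps
    d = genotypes.dosage
    out = np.full((m, m), np.nan)
    np.fill_diagonal(out, 1.0)
    for j in range(m):
        for k in range(j + 1, m):
            ok = ~np.isnan(d[:, j]) & ~np.isnan(d[:, k])
            x, y = d[ok, j], d[ok, k]
            if len(x) < 2 or x.std() == 0 or y.std() == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            out[j, k] = out[k, j] = r * r
    return pd.DataFrame(out, index=genotypes.rsids, columns=genotypes.rsids)


def prune_priority(metrics: QCMetrics) -> list[str]:
    """Deterministic pruning order: ascending screen p (NaN last), then
    descending MAF, then lexicographic rsid."""
    t = metrics.per_snp.copy()
    if "screen_p" not in t.columns:
        t["screen_p"] = np.nan
    t = t.reset_index(names="rsid")
    t["p_key"] = t["screen_p"].fillna(np.inf)
    t = t.sort_values(["p_key", "maf", "rsid"], ascending=[True, False, True])
    return t["rsid"].tolist()


def ld_prune(r2: pd.DataFrame, priority: list[str], threshold: float = LD_R2_MAX) -> list[str]:
    """Greedy tag-SNP selection.

    Visits SNPs in ``priority`` order and keeps a SNP iff its r^2 with every
    already-kept SNP is strictly below ``threshold``.  NaN r^2 (zero-variance
    pair) never blocks retention.  Returns kept rsids in priority order;
    idempotent by construction.
    """
    kept: list[str] = []
    for rsid in priority:
        if rsid not in r2.index:
            continue
        vals = r2.loc[rsid, kept].to_numpy(dtype=float) if kept else np.array([])
        if not (vals[~np.isnan(vals)] >= threshold).any():
            kept.append(rsid)
    return kept


def screen_snps(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    alpha: float = SCREEN_ALPHA,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-SNP adjusted logistic screen.

    For each SNP fits obesity ~ dosage + age + sex + T2DM by maximum
    likelihood on that SNP's complete cases and reports the Wald p-value of
    the dosage coefficient.  SNPs that cannot be fit (constant dosage,
    separation, non-convergence) are flagged unscreenable and excluded.

    Returns (screen table indexed by rsid with columns ``screen_p``,
    ``dosage_or``, ``n``, ``status``) and the retained rsid list (p < alpha,
    strict).
    """
    pheno = phenotypes.data.set_index("id").loc[[str(p) for p in genotypes.participants]]
    covars = pheno[["age", "sex_female", "t2dm"]].to_numpy(dtype=float)
    y_all = pheno["obesity"].to_numpy(dtype=float)

    rows = []
    retained = []
    for j, rsid in enumerate(genotypes.rsids):
        dos = genotypes.dosage[:, j]
        ok = ~np.isnan(dos)
        x = np.column_stack([np.ones(ok.sum()), dos[ok], covars[ok]])
        y = y_all[ok]
        record = {"rsid": rsid, "screen_p": np.nan, "dosage_or": np.nan, "n": int(ok.sum())}
        if ok.sum() == 0 or np.ptp(dos[ok]) == 0:
            record["status"] = "unscreenable: constant or empty dosage"
        else:
            try:
                fit = sm.Logit(y, x).fit(disp=0, maxiter=100, tol=1e-8)
                coef, bse = fit.params[1], fit.bse[1]
                if not fit.mle_retvals.get("converged", False):
                    raise FitError("no convergence")
                if not np.isfinite(bse) or abs(coef) > 15:
                    raise FitError("separation suspected")
                record["screen_p"] = float(fit.pvalues[1])
                record["dosage_or"] = float(np.exp(coef))
                record["status"] = "ok"
            except Exception as exc:  # statsmodels raises several types here
                record["status"] = f"unscreenable: {exc}"
        rows.append(record)
        if record["status"] == "ok" and record["screen_p"] < alpha:
            retained.append(rsid)
    table = pd.DataFrame(rows).set_index("rsid")
    return table, retained
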