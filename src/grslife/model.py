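"""The top-level modelling surface.

:class:`GRSLifestyleModel` bundles a genotype matrix, SNP weight panel and
phenotype table; :meth:`GRSLifestyleModel.fit` runs the whole analysis —
panel QC, weighted-score construction, quartile stratification, the
association battery and the descriptive split — and returns a
:class:`GRSLifestyleResults` carrying every estimate with its 95% CI,
diagnostics, and a text ``summary()``.

Typical use::

    from grslife import GRSLifestyleModel, SimConfig, simulate_cohort

    cohort = simulate_cohort(SimConfig(seed=7))
    results = GRSLifestyleModel.from_cohort(cohort).fit()
    print(results.summary())
    results.save("report/")
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from . import qc
from .descriptives import describe_cohort
from .errors import InputError
from .genotypes import GenotypeMatrix, read_genotypes
from .grs import QUARTILE_LABELS, GRSResult, assign_quartiles, compute_grs
from .panel import SNPPanel, default_panel
from .phenotypes import PhenotypeTable

# which exposure level the cross-quartile comparison column conditions on
_CROSS_QUARTILE_LEVEL = {"pa": 0, "ehs": 1, "ssb": 1, "wine": 0}


@dataclass
class GRSLifestyleModel:
    """Weighted GRS / gene-lifestyle interplay model for one cohort.

    Parameters
    ----------
    genotypes, panel, phenotypes
        Effect-allele dosages (column order = panel order), the SNP weight
        panel, and the validated phenotype table.
    maf_min, call_rate_min, screen_alpha, ld_r2_max
        QC thresholds; defaults are MAF > 0.01, call rate >= 0.95, screen
        p < 0.05, LD r^2 < 0.8.  All comparisons follow the strict/inclusive
        boundary semantics documented in :mod:`grslife.qc`.
    exposures
        Lifestyle contrasts to analyse (subset of pa/ehs/ssb/wine).
    """

    genotypes: GenotypeMatrix
    panel: SNPPanel
    phenotypes: PhenotypeTable
    maf_min: float = qc.MAF_MIN
    call_rate_min: float = qc.CALL_RATE_MIN
    screen_alpha: float = qc.SCREEN_ALPHA
    ld_r2_max: float = qc.LD_R2_MAX
    exposures: tuple = ("pa", "ehs", "ssb", "wine")

    def __post_init__(self) -> None:
        if self.genotypes.rsids != self.panel.rsids:
            raise InputError("genotype column order must match the panel")
        ids = set(self.phenotypes.ids)
        missing = [p for p in self.genotypes.participants if p not in ids]
        if missing:
            raise InputError(f"phenotypes missing for genotyped participants: {missing[:5]}")

    @classmethod
    def from_cohort(cls, cohort, panel: SNPPanel | None = None, **kwargs) -> "GRSLifestyleModel":
        """Build from a :class:`~grslife.simulate.SyntheticCohort`."""
        if panel is None:
            panel = default_panel()
            if panel.rsids != cohort.genotypes.rsids:
                raise InputError("cohort SNPs do not match the default panel; pass a panel")
        return cls(cohort.genotypes, panel, cohort.phenotypes, **kwargs)

    @classmethod
    def from_files(cls, genotype_path, panel_path, phenotype_path, **kwargs) -> "GRSLifestyleModel":
        """Build from a VCF (or dosage CSV), a panel TSV and a phenotype CSV."""
        panel = SNPPanel.from_tsv(panel_path)
        genotypes = read_genotypes(genotype_path, panel)
        phenotypes = PhenotypeTable.from_csv(phenotype_path)
        return cls(genotypes, panel, phenotypes, **kwargs)

    # ------------------------------------------------------------------
    def run_qc(self) -> dict:
        """MAF/call-rate filter, adjusted logistic screen, LD pruning.

        Returns a dict with the QC report table, the final tag-SNP list (in
        panel order) and the participant-exclusion count under the
        drop-any-missing policy.
        """
        metrics = qc.compute_maf(self.genotypes)
        kept_basic, exclusions = qc.filter_snps(metrics, self.maf_min, self.call_rate_min)
        geno = self.genotypes.subset_snps(kept_basic)

        if kept_basic:
            screen_table, kept_screen = qc.screen_snps(geno, self.phenotypes, self.screen_alpha)
        else:
            screen_table = pd.DataFrame(
                columns=["screen_p", "dosage_or", "n", "status"],
                index=pd.Index([], name="rsid"))
            kept_screen = []
        geno = geno.subset_snps(kept_screen)

        kept_final: list[str] = []
        r2 = None
        if len(kept_screen) >= 2:
            r2 = qc.pairwise_r2(geno)
            pruning_metrics = qc.QCMetrics(
                per_snp=metrics.per_snp.loc[kept_screen].join(screen_table[["screen_p"]]))
            priority = qc.prune_priority(pruning_metrics)
            kept_final = qc.ld_prune(r2, priority, self.ld_r2_max)
        else:
            kept_final = list(kept_screen)
        # restore panel order for the final tag set
        kept_final = [rs for rs in self.panel.rsids if rs in set(kept_final)]

        report = metrics.per_snp.copy()
        report = report.join(screen_table[["screen_p", "status"]], how="left")
        report["retained"] = report.index.isin(kept_final)
        reason = pd.Series("", index=report.index)
        for _, row in exclusions.iterrows():
            reason[row["rsid"]] = row["reason"]
        unscreened = report.index[
            report["status"].notna() & (report["status"] != "ok")]
        reason[unscreened] = report.loc[unscreened, "status"]
        failed_screen = report.index[
            (report["status"] == "ok") & ~(report["screen_p"] < self.screen_alpha)]
        reason[failed_screen] = "screen p >= alpha"
        pruned = report.index[(reason == "") & ~report["retained"]]
        reason[pruned] = f"LD-pruned (r^2 >= {self.ld_r2_max})"
        report["reason"] = reason

        masked = self.genotypes.subset_snps(kept_final)
        n_dropped = int(masked.missing_mask.any(axis=1).sum()) if kept_final else 0
        return {
            "report": report,
            "retained": kept_final,
            "r2": r2,
            "n_participants_dropped": n_dropped,
        }

    def fit(self) -> "GRSLifestyleResults":
        """Run QC, scoring, stratification and the full association battery."""
        qc_out = self.run_qc()
        retained = qc_out["retained"]
        if not retained:
            raise InputError("no SNPs survive QC: cannot construct a score")
        panel = self.panel.subset(retained)
        geno = self.genotypes.subset_snps(retained).complete_cases()
        scores = assign_quartiles(compute_grs(geno, panel))

        pheno = self.phenotypes
        obesity_or = assoc.fit_obesity_logistic(scores, pheno)
        bmi_slope = assoc.fit_bmi_linear(scores, pheno)
        quartile_or = assoc.grs_quartile_obesity_trend(scores, pheno)
        quartile_bmi = assoc.quartile_bmi_contrasts(scores, pheno)

        exposure_tables = {}
        cross_quartile = {}
        for exposure in self.exposures:
            exposure_tables[exposure] = assoc.within_quartile_exposure_effect(
                scores, pheno, exposure)
            cross_quartile[exposure] = assoc.quartile_bmi_contrasts(
                scores, pheno, stratum=(exposure, _CROSS_QUARTILE_LEVEL[exposure]))

        frame = assoc.build_analysis_frame(scores, pheno)
        descriptives = describe_cohort(frame)

        return GRSLifestyleResults(
            model=self,
            qc_report=qc_out["report"],
            retained_snps=retained,
            n_participants_dropped=qc_out["n_participants_dropped"],
            scores=scores,
            obesity_or=obesity_or,
            bmi_slope=bmi_slope,
            quartile_or=quartile_or,
            quartile_bmi=quartile_bmi,
            exposure_tables=exposure_tables,
            cross_quartile=cross_quartile,
            descriptives=descriptives,
        )


@dataclass
class GRSLifestyleResults:
    """Fitted estimates, stratified contrasts and diagnostics.

    Attributes mirror the analysis battery: ``obesity_or`` (logistic OR per
    score unit), ``bmi_slope`` (OLS slope + R^2), ``quartile_or`` (Q2-Q4 vs
    Q1), ``quartile_bmi`` (pairwise Welch contrasts, Bonferroni m=6),
    ``exposure_tables`` (per-exposure within-quartile contrasts),
    ``cross_quartile`` (quartile contrasts inside the analysis stratum of
    each exposure) and ``descriptives`` (baseline table).
    """

    model: GRSLifestyleModel
    qc_report: pd.DataFrame = field(repr=False)
    retained_snps: list
    n_participants_dropped: int
    scores: GRSResult = field(repr=False)
    obesity_or: assoc.EffectEstimate
    bmi_slope: assoc.EffectEstimate
    quartile_or: dict
    quartile_bmi: assoc.ComparisonSet = field(repr=False)
    exposure_tables: dict = field(repr=False)
    cross_quartile: dict = field(repr=False)
    descriptives: pd.DataFrame = field(repr=False)

    # ------------------------------------------------------------------
    def quartile_sizes(self) -> dict:
        counts = self.scores.quartile.value_counts()
        return {q: int(counts.get(q, 0)) for q in QUARTILE_LABELS}

    def exposure_frame(self, exposure: str) -> pd.DataFrame:
        """Within-quartile exposure contrasts as a flat table (one row per
        quartile), in the layout of the stratified report tables."""
        rows = []
        cross = self.cross_quartile[exposure].contrasts.set_index("pair")
        for comp in self.exposure_tables[exposure]:
            est = comp.or_within
            row = {
                "quartile": comp.quartile,
                "n": comp.n_exposed + comp.n_unexposed,
                "n_exposed": comp.n_exposed,
                "mean_exposed": comp.mean_exposed,
                "sd_exposed": comp.sd_exposed,
                "n_unexposed": comp.n_unexposed,
                "mean_unexposed": comp.mean_unexposed,
                "sd_unexposed": comp.sd_unexposed,
                "diff": comp.diff,
                "diff_ci_low": comp.diff_ci[0],
                "diff_ci_high": comp.diff_ci[1],
                "or": est.point if est else np.nan,
                "or_ci_low": est.ci_low if est else np.nan,
                "or_ci_high": est.ci_high if est else np.nan,
                "or_p": est.p if est else np.nan,
                "note": comp.note,
            }
            for other in QUARTILE_LABELS:
                if other == comp.quartile:
                    continue
                pair = f"{max(comp.quartile, other)} vs {min(comp.quartile, other)}"
                if pair in cross.index:
                    row[f"p_bonf_vs_{other}"] = cross.loc[pair, "p_bonferroni"]
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable multi-section summary of the fitted analysis."""
        e1, e2 = self.obesity_or, self.bmi_slope
        lines = [
            "Weighted GRS / lifestyle interplay analysis",
            "=" * 46,
            f"Participants scored: {len(self.scores.scores)} "
            f"(dropped for missing genotypes: {self.n_participants_dropped})",
            f"SNPs retained after QC: {len(self.retained_snps)} "
            f"of {len(self.model.panel)}: {', '.join(self.retained_snps)}",
            f"GRS quartile cutpoints (25/50/75): "
            + ", ".join(f"{c:.4f}" for c in self.scores.cutpoints),
            f"Quartile sizes: {self.quartile_sizes()}",
            "",
            "Obesity ~ GRS (adjusted for age, sex, T2DM):",
            f"  OR per GRS unit = {e1.point:.3f} "
            f"(95% CI {e1.ci_low:.3f}-{e1.ci_high:.3f}), p = {e1.p:.3g}, n = {e1.n}",
            "BMI ~ GRS (OLS):",
            f"  slope = {e2.point:.3f} kg/m^2 per GRS unit "
            f"(95% CI {e2.ci_low:.3f}-{e2.ci_high:.3f}), "
            f"R^2 = {e2.r_squared:.3f}, p = {e2.p:.3g}",
            "",
            "Obesity OR by GRS quartile (vs Q1, adjusted):",
        ]
        for q, est in self.quartile_or.items():
            lines.append(f"  {q}: OR = {est.point:.3f} "
                         f"(95% CI {est.ci_low:.3f}-{est.ci_high:.3f}), p = {est.p:.3g}")
        for exposure in self.model.exposures:
            lines.append("")
            lines.append(f"Within-quartile contrasts, exposure = {exposure}:")
            for comp in self.exposure_tables[exposure]:
                if comp.or_within is None:
                    lines.append(f"  {comp.quartile}: {comp.note or 'not estimable'}")
                    continue
                est = comp.or_within
                lines.append(
                    f"  {comp.quartile}: BMI {comp.mean_exposed:.1f}±{comp.sd_exposed:.2f} vs "
                    f"{comp.mean_unexposed:.1f}±{comp.sd_unexposed:.2f}, "
                    f"diff = {comp.diff:+.2f} "
                    f"({comp.diff_ci[0]:.2f}-{comp.diff_ci[1]:.2f}); "
                    f"OR = {est.point:.2f} ({est.ci_low:.2f}-{est.ci_high:.2f})")
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def save(self, out_dir) -> dict:
        """Write the report bundle (TSV tables + JSON summary) to a directory.

        Deterministic: identical inputs produce byte-identical files.
        Returns the name -> path mapping.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}

        def _tsv(name: str, frame: pd.DataFrame, index=False, label=None):
            p = out / f"{name}.tsv"
            frame.to_csv(p, sep="\t", index=index, index_label=label, float_format="%.6g")
            paths[name] = p

        _tsv("qc_report", self.qc_report, index=True, label="rsid")
        _tsv("table1_descriptives", self.descriptives)
        self.scores.to_tsv(out / "scores.tsv")
        paths["scores"] = out / "scores.tsv"
        for i, exposure in enumerate(self.model.exposures, start=2):
            _tsv(f"table{i}_{exposure}", self.exposure_frame(exposure))
        _tsv("quartile_bmi_contrasts", self.quartile_bmi.contrasts)

        summary = {
            "n_scored": len(self.scores.scores),
            "n_participants_dropped": self.n_participants_dropped,
            "retained_snps": list(self.retained_snps),
            "cutpoints": list(self.scores.cutpoints),
            "quartile_sizes": self.quartile_sizes(),
            "obesity_or": self.obesity_or.__dict__,
            "bmi_slope": self.bmi_slope.__dict__,
            "quartile_or": {q: e.__dict__ for q, e in self.quartile_or.items()},
            "bonferroni_family_size": self.quartile_bmi.m,
        }
        p = out / "summary.json"
        with open(p, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        paths["summary"] = p
        return paths
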