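"""Synthetic cohort generator.

Generates genotype + phenotype cohorts with the statistical structure the
downstream analysis assumes, so the full pipeline is testable without access
to any registry data.

Genotypes
---------
Each SNP's dosage is the count of its risk allele over two haplotypes.
Independent SNPs are Binomial(2, MAF) — Hardy-Weinberg by construction.
Linkage disequilibrium is induced with a Gaussian copula: within a block the
two haplotypes each carry a latent exchangeable-correlation multivariate
normal, thresholded at each SNP's MAF quantile, which preserves every
marginal allele frequency exactly while correlating dosages.

Phenotypes
----------
BMI follows an additive liability-style model,

    BMI_i = baseline + sum_j beta_j g_ij + sum_k effect_k x_ik
            + sum_k ic_k z(GRS_i) x_ik + N(0, bmi_sd^2),

with obesity defined as BMI >= 30.  ``z(GRS)`` is the within-cohort z-score
of the true weighted risk score, so interaction coefficients are kg/m^2 per
(risk-score SD x exposure).  Height is drawn and weight back-solved from BMI,
type-2 diabetes is Bernoulli with a logistic link on BMI, and lifestyle
exposures follow configured prevalences.

A single global seed expands into fixed per-stage substreams (genotypes,
missingness, exposures, noise), so each stage can be regenerated
independently and identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, InputError
from .genotypes import GenotypeMatrix, write_dosage_csv, write_vcf
from .panel import SNPPanel, default_panel
from .phenotypes import PhenotypeTable

# fixed substream labels: stage index is hashed into the seed sequence
_STAGES = {"genotypes": 0, "missing": 1, "exposures": 2, "noise": 3}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STAGES[stage],)))


@dataclass
class SimConfig:
    """Generating parameters for a synthetic cohort.

    Defaults reproduce the study conditions of a large adult cohort
    (n = 5824): age 55.78 +/- 15.3 y, 69.54% female, height 166.42 +/- 9.15
    cm, ~54.5% obesity prevalence, T2DM prevalence ~7.7% rising with BMI,
    19.95% physically active (>= 90 min/week), 11.74% SSB consumers, 24%
    moderate wine drinkers with 2.5% missing wine data, and an 8-SNP risk
    panel whose per-allele BMI effects are 3.067 x the panel weights so the
    BMI-on-GRS regression has slope ~3.067 and R^2 ~0.02.
    """

    n_participants: int = 5824
    snp_mafs: list = field(default_factory=lambda: [0.17, 0.12, 0.41, 0.24, 0.45, 0.28, 0.22, 0.18])
    ld_blocks: list = field(default_factory=lambda: [([5, 7], 0.4)])  # the two BDNF SNPs
    per_allele_betas: list = field(default_factory=lambda: [
        3.067 * w for w in (0.13, 0.10, 0.25, 0.16, 0.14, 0.12, 0.15, 0.17)])
    baseline_bmi_mean: float = 28.64
    bmi_sd: float = 5.85  # residual (non-genetic, non-lifestyle) SD
    lifestyle_prevalences: dict = field(default_factory=lambda: {
        "active": 0.1995, "ssb": 0.1174, "wine": 0.24})
    ehs_item_count: int = 8
    ehs_likert_max: int = 4
    ehs_score_mean: float = 11.60
    ehs_score_sd: float = 7.55
    lifestyle_effects: dict = field(default_factory=lambda: {
        "active": -2.4, "ehs_high": 1.1, "ssb": 1.7, "wine": -1.2})
    interaction_coefs: dict = field(default_factory=lambda: {
        "active": -0.2, "ehs_high": 0.1, "ssb": 0.2, "wine": -0.2})
    age_mean: float = 55.78
    age_sd: float = 15.3
    female_prob: float = 0.6954
    height_mean_cm: float = 166.42
    height_sd_cm: float = 9.15
    t2dm_intercept: float = -3.9
    t2dm_slope: float = 0.045
    wine_missing_rate: float = 0.025
    missing_geno_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ConfigError("n_participants must be positive")
        mafs = np.asarray(self.snp_mafs, dtype=float)
        if not ((mafs > 0) & (mafs <= 0.5)).all():
            raise ConfigError("all MAFs must lie in (0, 0.5]")
        if len(self.per_allele_betas) != len(self.snp_mafs):
            raise ConfigError("per_allele_betas and snp_mafs lengths differ")
        for idx_set, rho in self.ld_blocks or []:
            if not (0 <= rho < 1):
                raise ConfigError(f"LD rho must lie in [0, 1), got {rho}")
            if any(i < 0 or i >= len(self.snp_mafs) for i in idx_set):
                raise ConfigError(f"LD block index out of range: {idx_set}")
        probs = [self.female_prob, self.missing_geno_rate, self.wine_missing_rate,
                 *self.lifestyle_prevalences.values()]
        if not all(0 <= p <= 1 for p in probs):
            raise ConfigError("all probabilities must lie in [0, 1]")
        if self.missing_geno_rate >= 1:
            raise ConfigError("missing_geno_rate must be < 1")
        if self.bmi_sd <= 0:
            raise ConfigError("bmi_sd must be positive")
        if self.ehs_item_count < 1 or self.ehs_likert_max < 1:
            raise ConfigError("EHS item count and Likert maximum must be >= 1")

    @property
    def n_snps(self) -> int:
        return len(self.snp_mafs)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["ld_blocks"] = [[list(ix), rho] for ix, rho in (self.ld_blocks or [])]
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if d.get("ld_blocks"):
            d["ld_blocks"] = [(list(ix), float(rho)) for ix, rho in d["ld_blocks"]]
        return cls(**d)


@dataclass
class SyntheticCohort:
    """A simulated cohort plus the generating truth (for recovery tests)."""

    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    truth: dict

    def __post_init__(self) -> None:
        if self.genotypes.n_participants != self.phenotypes.n:
            raise InputError("genotype and phenotype row counts differ")


def simulate_genotypes(config: SimConfig, *, apply_missingness: bool = True) -> GenotypeMatrix:
    """Draw the cohort's risk-allele dosage matrix.

    SNPs outside any LD block are independent Binomial(2, MAF); block members
    share a latent exchangeable-correlation normal per haplotype, thresholded
    at Phi^-1(MAF), which leaves each marginal MAF exact.  Missing calls are
    masked at ``missing_geno_rate`` unless ``apply_missingness`` is False.
    """
    rng = _rng(config.seed, "genotypes")
    n, m = config.n_participants, config.n_snps
    mafs = np.asarray(config.snp_mafs, dtype=float)
    dosage = np.empty((n, m), dtype=float)

    in_block = set()
    for idx_set, _ in config.ld_blocks or []:
        in_block.update(idx_set)
    indep = [j for j in range(m) if j not in in_block]
    if indep:
        dosage[:, indep] = rng.binomial(2, mafs[indep], size=(n, len(indep)))

    for idx_set, rho in config.ld_blocks or []:
        idx = list(idx_set)
        thresh = stats.norm.ppf(mafs[idx])
        block = np.zeros((n, len(idx)))
        for _hap in range(2):  # two haplotypes per diploid participant
            shared = rng.standard_normal((n, 1))
            private = rng.standard_normal((n, len(idx)))
            latent = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * private
            block += (latent < thresh)
        dosage[:, idx] = block

    if apply_missingness and config.missing_geno_rate > 0:
        miss_rng = _rng(config.seed, "missing")
        mask = miss_rng.random((n, m)) < config.missing_geno_rate
        dosage[mask] = np.nan

    participants = [f"P{i + 1:05d}" for i in range(n)]
    rsids = default_panel().rsids if m == 8 else [f"snp{j + 1}" for j in range(m)]
    return GenotypeMatrix(dosage, participants, rsids)


def _spread_ehs_items(scores: np.ndarray, n_items: int, likert_max: int) -> np.ndarray:
    """Deterministically split integer scores across Likert items.

    Each item gets the integer base ``score // n_items``; the remainder is
    added one point at a time to the leading items.  Values stay within
    [0, likert_max] because scores are pre-clipped to the attainable range.
    """
    base, rem = np.divmod(scores.astype(int), n_items)
    items = np.tile(base[:, None], (1, n_items))
    bump = np.arange(n_items)[None, :] < rem[:, None]
    items = items + bump
    return np.clip(items, 0, likert_max)


def simulate_phenotypes(genotypes: GenotypeMatrix, config: SimConfig) -> PhenotypeTable:
    """Draw phenotypes and lifestyle variables given complete genotypes.

    Requires a complete dosage matrix (generate phenotypes before masking
    missing calls); raises :class:`InputError` otherwise or on a row-count
    mismatch with the configuration.
    """
    if genotypes.n_participants != config.n_participants:
        raise InputError("genotype rows do not match n_participants")
    if genotypes.missing_mask.any():
        raise InputError("phenotype simulation needs complete genotypes")

    exp_rng = _rng(config.seed, "exposures")
    noise_rng = _rng(config.seed, "noise")
    n = config.n_participants
    g = genotypes.dosage
    betas = np.asarray(config.per_allele_betas, dtype=float)

    age = np.clip(exp_rng.normal(config.age_mean, config.age_sd, n), 18, 100)
    female = exp_rng.binomial(1, config.female_prob, n)
    height = exp_rng.normal(config.height_mean_cm, config.height_sd_cm, n)

    prev = config.lifestyle_prevalences
    active = exp_rng.binomial(1, prev["active"], n)
    # integer minutes; inactive strictly below the 90 min/week threshold
    pa_min = np.where(
        active == 1,
        np.ceil(90.0 + exp_rng.exponential(120.0, n)),
        exp_rng.integers(0, 90, n),
    )

    max_score = config.ehs_item_count * config.ehs_likert_max
    raw = exp_rng.normal(config.ehs_score_mean, config.ehs_score_sd, n)
    ehs_score = np.clip(np.rint(raw), 0, max_score)
    ehs_items = _spread_ehs_items(ehs_score, config.ehs_item_count, config.ehs_likert_max)
    ehs_high = (ehs_score >= np.median(ehs_score)).astype(int)

    ssb_consumer = exp_rng.binomial(1, prev["ssb"], n)
    ssb_cups = np.where(ssb_consumer == 1, 1 + exp_rng.poisson(0.7, n), 0).astype(float)

    wine_moderate = exp_rng.binomial(1, prev["wine"], n)
    wine_drinks = np.where(wine_moderate == 1, exp_rng.integers(1, 4, n), 0).astype(float)
    wine_missing = exp_rng.random(n) < config.wine_missing_rate
    wine_drinks[wine_missing] = np.nan

    grs_true = g @ betas  # true weighted risk score on the kg/m^2 scale
    sd = grs_true.std(ddof=0)
    z = (grs_true - grs_true.mean()) / sd if sd > 0 else np.zeros(n)

    exposures = {"active": active, "ehs_high": ehs_high,
                 "ssb": ssb_consumer, "wine": wine_moderate}
    bmi = config.baseline_bmi_mean + g @ betas
    for name, x in exposures.items():
        bmi = bmi + config.lifestyle_effects[name] * x
        bmi = bmi + config.interaction_coefs[name] * z * x
    bmi = bmi + noise_rng.normal(0.0, config.bmi_sd, n)
    bmi = np.clip(bmi, 14.0, None)  # floor: lower BMI is not survivable

    weight = bmi * (height / 100.0) ** 2
    p_t2dm = 1.0 / (1.0 + np.exp(-(config.t2dm_intercept + config.t2dm_slope * bmi)))
    t2dm = noise_rng.binomial(1, p_t2dm)

    data = pd.DataFrame({
        "id": genotypes.participants,
        "height_cm": height.round(1),
        "weight_kg": weight,
        "age": age.round(1),
        "sex": np.where(female == 1, "female", "male"),
        "t2dm": t2dm,
        "pa_min_week": pa_min,
        "ssb_cups_day": ssb_cups,
        "wine_drinks_week": wine_drinks,
    })
    for k in range(config.ehs_item_count):
        data[f"ehs_item_{k + 1}"] = ehs_items[:, k]
    # back-solve weight so the derived BMI reproduces the generated one exactly
    data["weight_kg"] = (bmi * (data["height_cm"] / 100.0) ** 2).round(6)
    return PhenotypeTable(data)


def simulate_cohort(config: SimConfig, panel: SNPPanel | None = None) -> SyntheticCohort:
    """Generate a full cohort: complete genotypes drive phenotypes, then
    genotype missingness is masked in the released matrix."""
    complete = simulate_genotypes(config, apply_missingness=False)
    phenotypes = simulate_phenotypes(complete, config)
    released = simulate_genotypes(config)
    return SyntheticCohort(released, phenotypes, truth=config.to_dict())


def write_cohort(cohort: SyntheticCohort, out_prefix, panel: SNPPanel | None = None) -> dict:
    """Write VCF + phenotype CSV + truth JSON under ``out_prefix``.

    Returns the mapping of artifact name to path.  The VCF carries the effect
    allele as ALT and ``./.`` for missing calls; the round trip through the
    readers reproduces the dosage matrix exactly.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if panel is None:
        panel = default_panel()
        if panel.rsids != cohort.genotypes.rsids:
            if cohort.genotypes.n_snps > len(panel):
                raise InputError("no default panel for >8 SNPs; pass one explicitly")
            t = panel.table.iloc[: cohort.genotypes.n_snps].copy()
            t["rsid"] = cohort.genotypes.rsids
            panel = SNPPanel(t.reset_index(drop=True))
    paths = {
        "vcf": prefix.with_suffix(".vcf"),
        "phenotypes": Path(str(prefix) + "_phenotypes.csv"),
        "dosages": Path(str(prefix) + "_dosages.csv"),
        "truth": Path(str(prefix) + "_truth.json"),
    }
    write_vcf(cohort.genotypes, panel, paths["vcf"])
    write_dosage_csv(cohort.genotypes, paths["dosages"])
    cohort.phenotypes.to_csv(paths["phenotypes"])
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def read_cohort(prefix, panel: SNPPanel) -> SyntheticCohort:
    """Read back a cohort written by :func:`write_cohort`."""
    from .genotypes import read_vcf

    prefix = Path(prefix)
    genotypes = read_vcf(prefix.with_suffix(".vcf"), panel)
    phenotypes = PhenotypeTable.from_csv(str(prefix) + "_phenotypes.csv")
    with open(str(prefix) + "_truth.json") as fh:
        truth = json.load(fh)
    return SyntheticCohort(genotypes, phenotypes, truth)
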