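# Methods

## The analysis model

`grslife` analyses the joint contribution of a weighted polygenic score and
lifestyle exposures to obesity in a cross-sectional adult cohort.

**Score.** For a panel of SNPs with risk alleles and per-allele weights
β_j, each participant's score is GRS_i = Σ_j g_ij β_j with g_ij ∈ {0,1,2}
the risk-allele dosage. Negative user-supplied weights are re-oriented at
panel load (allele swap + sign flip), so all weights are non-negative and
higher score always means higher predicted BMI. Participants with any
missing panel dosage are dropped before scoring (complete-case policy,
count logged); a missing dosage reaching the scorer is treated as a policy
violation, not silently imputed.

**Quartiles.** Cutpoints are the 25th/50th/75th linear-interpolation
percentiles of the scored cohort. Boundary values go to the lower quartile
(Q1: grs ≤ c25; Q2: c25 < grs ≤ c50; …), so tied scores always share a
label and quartile sizes deviate from n/4 only by cutpoint ties. Quartiles
are assigned once on the full scored cohort and never recomputed inside
lifestyle strata: stratified tables differ in n only through stratum
missingness.

**Panel QC.** Selection order: (1) MAF filter, strictly > 0.01, with MAF =
min(f, 1−f) and f the effect-allele frequency over non-missing calls;
(2) call-rate filter, ≥ 0.95 by default ("significant missingness" is not a
standardised quantity, so the threshold is configurable and echoed in the
report); (3) per-SNP logistic screen obesity ~ dosage + age + sex + T2DM,
retaining Wald p strictly < 0.05; (4) LD pruning at r² strictly < 0.8.
Because hard genotypes carry no phase, LD is measured as composite
genotypic r² — the squared Pearson correlation of dosage vectors on
pairwise-complete observations; it is invariant to allele-orientation
flips. Pruning is greedy in a deterministic priority order (ascending
screen p, then descending MAF, then rsid), which keeps the most informative
member of each correlated cluster and makes the output reproducible; the
greedy result equals the priority-lexicographically first maximal
conflict-free subset, which the tests verify by exhaustive search on small
fixtures.

**Association battery.** All logistic models are fitted by maximum
likelihood (IRLS, tolerance 1e-8, ≤ 100 iterations); non-convergence and
separation (unbounded coefficients / infinite standard errors) surface as
explicit fit failures, never as silent estimates. Confidence intervals are
Wald on the log-odds or slope scale, 95% throughout. Group-mean BMI
comparisons use Welch's t-test (unequal variances, Satterthwaite df);
cross-quartile comparisons form a family of all 6 pairs with Bonferroni
adjustment p_adj = min(1, 6·p). Within-quartile exposure odds ratios are
adjusted for age, sex (female = 1) and T2DM; the BMI means, SDs and
differences beside them are crude, matching how stratified tables are
conventionally printed — both are labelled in the output. Each model is
complete-case; only wine analyses drop the wine-missing participants.

**Descriptives.** The baseline table maps variables to tests by
declaration, not normality inference: age/height/weight/BMI → t-test,
eating-habits score → Mann–Whitney, all flags → chi-square; the mapping is
configurable and echoed in the output. Percentages are always recomputed
as 100·count/denominator (2 dp in reports); the wine denominator defaults
to the full group n, with a complete-case switch.

## Lifestyle derivations

All thresholds boundary-inclusive: active = PA ≥ 90 min/week; high eating
habits score = item-sum ≥ cohort median (linear-interpolation median over
all scored participants — the flag is a cohort-level, not row-level,
function); SSB consumer = ≥ 1 cup/day; moderate wine = 1–3 drinks/week
inclusive, with missing wine propagated as its own flag. BMI =
weight/(height/100)², obesity = BMI ≥ 30 kg/m².

## The synthetic cohort generator

The generator exists so that every downstream stage is testable without
registry access; its defaults are the study conditions of a large adult
cohort and are not tuning knobs.

**Genotypes.** Independent SNPs are Binomial(2, MAF) — Hardy–Weinberg by
construction. LD blocks use a Gaussian copula: per haplotype, a latent
exchangeable-correlation (ρ) multivariate normal thresholded at Φ⁻¹(MAF).
This preserves every marginal allele frequency exactly while correlating
dosages, and is fully seedable; it makes no attempt to mimic real human LD
maps, population structure or imputation uncertainty. Calls are masked
missing at rate 0.002 per genotype (≈ 1.6% of participants lose ≥ 1 of 8
SNPs, emulating an exclusion of roughly 100 per 5824).

**Phenotypes.** BMI follows an additive liability-style model — baseline +
Σ β_j g_ij + Σ effect_k·exposure_k + Σ ic_k·z(GRS)·exposure_k + N(0, σ²) —
with obesity thresholded at 30. Interaction coefficients multiply the
within-cohort z-score of the true score, so they read as kg/m² per
(score-SD × exposure). T2DM is generated downstream of BMI through a
logistic link (intercept −3.9, slope 0.045 per BMI unit, solved from group
prevalences ≈ 9.0% obese / 6.2% non-obese, ≈ 7.7% overall), making it a
legitimate adjustment covariate rather than a collider. Height is drawn
N(166.42, 9.15²) cm and weight back-solved from BMI. A single global seed
expands into fixed per-stage substreams (genotypes, missingness, exposures,
noise), so any stage can be regenerated independently and a config + seed
pair reproduces the cohort byte-for-byte.

**Default conditions** (units; rationale):

| parameter | default | why |
|---|---|---|
| n_participants | 5824 | study-scale cohort |
| age | N(55.78, 15.3²) y, clipped 18–100 | cohort marginal |
| female_prob | 0.6954 | cohort marginal |
| active / SSB / wine prevalence | 0.1995 / 0.1174 / 0.24 | cohort marginals |
| wine_missing_rate | 0.025 | ≈ 146/5824 missing |
| EHS | 8 items, Likert 0–4; sum ≈ N(11.6, 7.55²), clipped | cohort marginal; items back-filled deterministically from the sum |
| panel weights | 0.10–0.25 (synthetic) | GWAS-like magnitudes |
| per_allele_betas | 3.067 × weight (kg/m² per allele) | makes the BMI-on-GRS slope ≈ 3.07 with R² ≈ 0.02 |
| lifestyle_effects | −2.4 (PA), +1.1 (EHS), +1.7 (SSB), −1.2 (wine) kg/m² | stratified BMI-difference magnitudes |
| interaction_coefs | −0.2, +0.1, +0.2, −0.2 kg/m² per SD×exposure | mild amplification at higher genetic risk |
| baseline_bmi_mean | 28.64 kg/m² | centres total BMI ≈ 30.7 so P(BMI ≥ 30) ≈ 54.5% |
| bmi_sd (residual) | 5.85 kg/m² | total SD ≈ 6.06 after genetic + lifestyle variance |

**Known limitation.** Real BMI is right-skewed; the Gaussian model cannot
simultaneously match a mean of 31.24, SD 6.06 *and* 54.5% above 30. The
defaults prioritise the obesity prevalence (and hence the logistic
analyses); the simulated mean BMI is ≈ 30.7, slightly below the target
marginal mean. Likewise, passing tests demonstrate statistical correctness
of the pipeline under this generative model — additive effects, Gaussian
noise, exposures independent of genotype — not robustness to confounding,
assortative structure, or self-report error in real questionnaire data.

## Numerical choices and degenerate inputs

- Score arithmetic is a plain dot product; linearity, monotonicity
  (adding one risk allele raises the score by exactly its β) and scale
  equivariance hold to float tolerance.
- All scores identical → quartile assignment refuses ("degenerate score
  distribution") rather than inventing cutpoints.
- Zero-variance dosage columns are "unscreenable" and excluded with a
  reason; zero-variance pairs get NaN r², which never blocks pruning.
- Stratum cells with n < 2 yield explicitly not-estimable contrasts, not
  exceptions, so one empty cell cannot kill a whole report.
- Report files use fixed float formatting and carry no timestamps, making
  the full bundle reproducible byte-for-byte from config + seed.

## Problem sizes used in validation

The test-suite simulations are sized for precision, not ceremony: genotype
marginal checks use 50k–200k draws; parameter-recovery runs 600 cohorts at
the full n = 5824 (Monte-Carlo sd of a coverage estimate ≈ 0.9%, well
inside the 90–98% acceptance band); the null calibration of the per-SNP
screen uses 1000 replicates at n = 2000; LD pruning is verified against
exhaustive subset search on panels of ≤ 10 SNPs, where enumeration is
exact.
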