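"""QC checks: dosage coding, MAF, filters, LD r^2 and pruning, screening."""

import numpy as np
import pandas as pd
import pytest

from grslife import (
    InputError,
    SNPPanel,
    compute_maf,
    filter_snps,
    ld_prune,
    pairwise_r2,
    screen_snps,
)
from grslife.genotypes import read_vcf
from grslife.qc import QCMetrics, prune_priority

from conftest import make_genotypes, make_phenotypes

VCF_TEMPLATE = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
{records}
"""


def write_vcf_text(tmp_path, records):
    path = tmp_path / "test.vcf"
    path.write_text(VCF_TEMPLATE.format(records="\n".join(records)))
    return path


def panel_one(effect="A", other="G"):
    return SNPPanel.from_frame(pd.DataFrame({
        "rsid": ["rs1"], "gene": ["G"], "effect_allele": [effect],
        "other_allele": [other], "beta": [0.2]}))


class TestDosageCoding:
    def test_alt_is_effect_allele(self, tmp_path):
        path = write_vcf_text(tmp_path, ["1\t1\trs1\tG\tA\t.\tPASS\t.\tGT\t1/1\t0/1\t0/0"])
        g = read_vcf(path, panel_one())
        np.testing.assert_array_equal(g.dosage[:, 0], [2, 1, 0])

    def test_ref_is_effect_allele_flips(self, tmp_path):
        path = write_vcf_text(tmp_path, ["1\t1\trs1\tA\tG\t.\tPASS\t.\tGT\t1/1\t0/1\t0/0"])
        g = read_vcf(path, panel_one())
        np.testing.assert_array_equal(g.dosage[:, 0], [0, 1, 2])

    def test_missing_call_masked(self, tmp_path):
        path = write_vcf_text(tmp_path, ["1\t1\trs1\tG\tA\t.\tPASS\t.\tGT\t./.\t0/1\t1/1"])
        g = read_vcf(path, panel_one())
        assert np.isnan(g.dosage[0, 0]) and g.dosage[1, 0] == 1

    def test_allele_mismatch_names_rsid(self, tmp_path):
        path = write_vcf_text(tmp_path, ["1\t1\trs1\tC\tT\t.\tPASS\t.\tGT\t0/0\t0/0\t0/0"])
        with pytest.raises(InputError, match="rs1"):
            read_vcf(path, panel_one())

    def test_multiallelic_rejected(self, tmp_path):
        path = write_vcf_text(tmp_path, ["1\t1\trs1\tG\tA,T\t.\tPASS\t.\tGT\t0/0\t0/0\t0/0"])
        with pytest.raises(InputError, match="multi-allelic"):
            read_vcf(path, panel_one())

    def test_flip_consistency_dosage_and_maf(self):
        # swapping effect/other alleles in the panel complements the dosage
        # and leaves the MAF unchanged
        rng = np.random.default_rng(0)
        dosage = rng.integers(0, 3, size=(200, 1)).astype(float)
        g = make_genotypes(dosage)
        g_flip = make_genotypes(2.0 - dosage)
        m, m_flip = compute_maf(g), compute_maf(g_flip)
        assert m.per_snp["maf"].iloc[0] == pytest.approx(m_flip.per_snp["maf"].iloc[0])
        np.testing.assert_array_equal(g_flip.dosage, 2.0 - g.dosage)


class TestMAF:
    def test_direct_count(self):
        g = make_genotypes([[0], [0], [1], [2]])
        m = compute_maf(g).per_snp
        assert m["effect_allele_freq"].iloc[0] == pytest.approx(0.375)
        assert m["maf"].iloc[0] == pytest.approx(0.375)

    def test_monomorphic(self):
        m = compute_maf(make_genotypes([[2], [2], [2]])).per_snp
        assert m["effect_allele_freq"].iloc[0] == 1.0
        assert m["maf"].iloc[0] == 0.0

    def test_monte_carlo_against_generating_frequency(self):
        rng = np.random.default_rng(1)
        g = make_genotypes(rng.binomial(2, 0.3, size=(10_000, 1)).astype(float))
        assert compute_maf(g).per_snp["maf"].iloc[0] == pytest.approx(0.3, abs=0.02)

    def test_all_missing_flagged(self):
        m = compute_maf(make_genotypes([[np.nan], [np.nan]])).per_snp
        assert m["all_missing"].iloc[0]
        assert np.isnan(m["maf"].iloc[0])

    def test_call_rate(self):
        g = make_genotypes([[0], [1], [np.nan], [2]])
        assert compute_maf(g).per_snp["call_rate"].iloc[0] == pytest.approx(0.75)


class TestFilter:
    def test_maf_boundary_strict(self):
        per_snp = pd.DataFrame({
            "maf": [0.009, 0.011, 0.010], "call_rate": [1.0, 1.0, 1.0],
            "all_missing": [False] * 3, "effect_allele_freq": [0.009, 0.011, 0.010]},
            index=["a", "b", "c"])
        retained, log = filter_snps(QCMetrics(per_snp=per_snp))
        assert retained == ["b"]  # 0.010 is excluded: threshold is strict
        assert set(log["rsid"]) == {"a", "c"}

    def test_call_rate_filter(self):
        per_snp = pd.DataFrame({
            "maf": [0.3, 0.3], "call_rate": [0.96, 0.90],
            "all_missing": [False, False], "effect_allele_freq": [0.3, 0.3]},
            index=["a", "b"])
        retained, log = filter_snps(QCMetrics(per_snp=per_snp))
        assert retained == ["a"]
        assert "call_rate" in log["reason"].iloc[0]

    def test_large_panel_count(self):
        # an 86-SNP panel with exactly 10 SNPs failing the MAF floor
        rng = np.random.default_rng(2)
        mafs = np.concatenate([rng.uniform(0.05, 0.5, 76), np.full(10, 0.005)])
        per_snp = pd.DataFrame({
            "maf": mafs, "call_rate": np.ones(86), "all_missing": np.zeros(86, bool),
            "effect_allele_freq": mafs}, index=[f"rs{i}" for i in range(86)])
        retained, _ = filter_snps(QCMetrics(per_snp=per_snp))
        assert len(retained) == 76


class TestPairwiseR2:
    def test_identical_vectors(self):
        d = np.array([[0, 0], [1, 1], [2, 2], [1, 1]], dtype=float)
        r2 = pairwise_r2(make_genotypes(d))
        assert r2.iloc[0, 1] == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        d = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        r2 = pairwise_r2(make_genotypes(d))
        assert r2.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, size=(50, 6)).astype(float)
        r2 = pairwise_r2(make_genotypes(d)).to_numpy()
        # brute-force oracle: element-by-element Pearson correlation
        for j in range(6):
            for k in range(6):
                x, y = d[:, j], d[:, k]
                mx, my = x.mean(), y.mean()
                num = ((x - mx) * (y - my)).sum()
                den = np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
                assert r2[j, k] == pytest.approx((num / den) ** 2, abs=1e-12)

    def test_symmetry_and_unit_diagonal(self):
        rng = np.random.default_rng(4)
        d = rng.integers(0, 3, size=(80, 5)).astype(float)
        r2 = pairwise_r2(make_genotypes(d)).to_numpy()
        np.testing.assert_allclose(r2, r2.T)
        np.testing.assert_allclose(np.diag(r2), 1.0)

    def test_zero_variance_flagged_nan(self):
        d = np.column_stack([np.ones(10) * 2, np.arange(10) % 3]).astype(float)
        r2 = pairwise_r2(make_genotypes(d))
        assert np.isnan(r2.iloc[0, 1])

    def test_r2_invariant_under_flip(self):
        rng = np.random.default_rng(5)
        d = rng.integers(0, 3, size=(100, 2)).astype(float)
        r2 = pairwise_r2(make_genotypes(d)).iloc[0, 1]
        d_flip = d.copy()
        d_flip[:, 0] = 2 - d_flip[:, 0]
        assert pairwise_r2(make_genotypes(d_flip)).iloc[0, 1] == pytest.approx(r2)


def _greedy_oracle(r2, priority, threshold):
    """Independent re-statement of prefix-greedy tag selection."""
    kept = []
    for rs in priority:
        if all(not (r2.loc[rs, k] >= threshold) for k in kept):
            kept.append(rs)
    return kept


class TestLDPrune:
    def test_two_correlated_snps_keep_higher_priority(self):
        r2 = pd.DataFrame([[1.0, 0.9], [0.9, 1.0]], index=["a", "b"], columns=["a", "b"])
        assert ld_prune(r2, ["b", "a"]) == ["b"]

    def test_all_below_threshold_all_kept(self):
        r2 = pd.DataFrame(np.eye(3) + 0.1, index=list("abc"), columns=list("abc"))
        np.fill_diagonal(r2.values, 1.0)
        assert ld_prune(r2, list("abc")) == ["a", "b", "c"]

    def test_block_of_three_keeps_six_of_eight(self):
        rsids = [f"rs{i}" for i in range(8)]
        m = np.full((8, 8), 0.05)
        np.fill_diagonal(m, 1.0)
        for i in (0, 1, 2):
            for j in (0, 1, 2):
                if i != j:
                    m[i, j] = 0.95
        r2 = pd.DataFrame(m, index=rsids, columns=rsids)
        kept = ld_prune(r2, rsids)
        assert len(kept) == 6
        assert kept == _greedy_oracle(r2, rsids, 0.8)

    def test_matches_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            m = rng.integers(2, 11)
            sym = rng.uniform(0, 1, size=(m, m))
            sym = (sym + sym.T) / 2
            np.fill_diagonal(sym, 1.0)
            rsids = [f"rs{i}" for i in range(m)]
            r2 = pd.DataFrame(sym, index=rsids, columns=rsids)
            priority = list(rng.permutation(rsids))
            assert ld_prune(r2, priority) == _greedy_oracle(r2, priority, 0.8)

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        sym = rng.uniform(0, 1, size=(9, 9))
        sym = (sym + sym.T) / 2
        np.fill_diagonal(sym, 1.0)
        rsids = [f"rs{i}" for i in range(9)]
        r2 = pd.DataFrame(sym, index=rsids, columns=rsids)
        kept = ld_prune(r2, rsids)
        assert ld_prune(r2.loc[kept, kept], kept) == kept

    def test_priority_order(self):
        per_snp = pd.DataFrame({
            "maf": [0.1, 0.4, 0.4], "screen_p": [0.03, np.nan, 0.001]},
            index=["a", "b", "c"])
        assert prune_priority(QCMetrics(per_snp=per_snp)) == ["c", "a", "b"]


class TestScreen:
    def test_constant_dosage_unscreenable(self):
        pheno = make_phenotypes(100)
        g = make_genotypes(np.ones((100, 1)), ids=pheno.ids)
        table, retained = screen_snps(g, pheno)
        assert retained == []
        assert table["status"].str.startswith("unscreenable").all()

    def test_strong_effect_retained(self):
        # generating per-allele OR 2.0 at MAF 0.3, n = 2000: essentially
        # always significant
        rng = np.random.default_rng(8)
        n = 2000
        dosage = rng.binomial(2, 0.3, n).astype(float)
        pheno = make_phenotypes(n, rng=rng)
        logit = -1.0 + np.log(2.0) * dosage
        obese = rng.binomial(1, 1 / (1 + np.exp(-logit)))
        data = pheno.data.copy()
        data["weight_kg"] = np.where(obese, 95.0, 75.0)  # BMI 32.9 vs 26
        pheno2 = make_phenotypes(n, rng=rng, weight_kg=data["weight_kg"])
        g = make_genotypes(dosage[:, None], ids=pheno2.ids)
        _, retained = screen_snps(g, pheno2)
        assert retained == ["rs1"]

    def test_wald_p_matches_independent_irls(self):
        # dual route: statsmodels-based screen vs a hand-rolled Newton-IRLS
        rng = np.random.default_rng(9)
        n = 500
        dosage = rng.binomial(2, 0.4, n).astype(float)
        pheno = make_phenotypes(n, rng=rng)
        g = make_genotypes(dosage[:, None], ids=pheno.ids)
        table, _ = screen_snps(g, pheno)
        d = pheno.data
        X = np.column_stack([np.ones(n), dosage, d["age"], d["sex_female"], d["t2dm"]])
        y = d["obesity"].to_numpy(dtype=float)
        beta = np.zeros(X.shape[1])
        for _ in range(50):
            eta = X @ beta
            mu = 1 / (1 + np.exp(-eta))
            W = mu * (1 - mu)
            grad = X.T @ (y - mu)
            hess = X.T @ (X * W[:, None])
            step = np.linalg.solve(hess, grad)
            beta = beta + step
            if np.abs(step).max() < 1e-12:
                break
        se = np.sqrt(np.linalg.inv(hess)[1, 1])
        from scipy import stats as ss
        p_oracle = 2 * ss.norm.sf(abs(beta[1] / se))
        assert table["screen_p"].iloc[0] == pytest.approx(p_oracle, abs=1e-6)
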