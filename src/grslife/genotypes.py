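"""Risk-allele dosage matrices and genotype I/O.

The central container is :class:`GenotypeMatrix`: participants x SNPs counts
of the panel's effect allele (0, 1 or 2), with NaN marking missing calls.
Column order always follows the panel order.

Hard genotypes come in as VCF 4.2 (GT field) read with cyvcf2, or as a
dosage CSV (participants x rsids, values 0/1/2 or empty).  Dosages are coded
against the panel: when the VCF ALT is the panel's effect allele the ALT
count is used directly; when REF is the effect allele the count is flipped
(2 - ALT count); any other allele combination is a validation error naming
the rsid.  Multi-allelic records are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .panel import SNPPanel

MISSING_GT = "./."


@dataclass
class GenotypeMatrix:
    """Participants x SNPs effect-allele dosages.

    ``dosage`` is a float array with values in {0, 1, 2} and NaN for missing
    calls; ``participants`` and ``rsids`` label the axes.
    """

    dosage: np.ndarray = field(repr=False)
    participants: list[str]
    rsids: list[str]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.participants), len(self.rsids)):
            raise InputError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.participants)} participants x {len(self.rsids)} SNPs"
            )
        observed = self.dosage[~np.isnan(self.dosage)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise InputError("dosages must be 0, 1 or 2 where not missing")

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def n_snps(self) -> int:
        return len(self.rsids)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask, True where the call is missing."""
        return np.isnan(self.dosage)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.participants, columns=self.rsids)

    def subset_snps(self, rsids) -> "GenotypeMatrix":
        """Columns restricted to ``rsids``, keeping current column order."""
        keep = [j for j, rs in enumerate(self.rsids) if rs in set(rsids)]
        return GenotypeMatrix(
            self.dosage[:, keep],
            list(self.participants),
            [self.rsids[j] for j in keep],
        )

    def complete_cases(self) -> "GenotypeMatrix":
        """Drop participants with any missing panel dosage."""
        keep = ~self.missing_mask.any(axis=1)
        return GenotypeMatrix(
            self.dosage[keep],
            [p for p, k in zip(self.participants, keep) if k],
            list(self.rsids),
        )


def read_dosage_csv(path, panel: SNPPanel) -> GenotypeMatrix:
    """Read a participants x rsids dosage CSV (first column = participant id).

    Panel SNPs absent from the file raise :class:`InputError`; extra columns
    are ignored.  Columns are reordered to the panel order.
    """
    frame = pd.read_csv(path, index_col=0)
    missing = [rs for rs in panel.rsids if rs not in frame.columns]
    if missing:
        raise InputError(f"dosage CSV missing panel SNPs: {missing}")
    frame = frame[panel.rsids]
    return GenotypeMatrix(
        frame.to_numpy(dtype=float),
        [str(i) for i in frame.index],
        panel.rsids,
    )


def read_vcf(path, panel: SNPPanel) -> GenotypeMatrix:
    """Read hard genotypes from a VCF and code them as effect-allele dosages.

    Only panel SNPs (matched by ID) are kept; panel SNPs absent from the VCF
    raise :class:`InputError`.  REF/ALT must equal the panel's allele pair in
    either orientation.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    by_rsid = {row.rsid: row for row in panel.table.itertuples()}
    columns: dict[str, np.ndarray] = {}
    for variant in vcf:
        rsid = variant.ID
        if rsid not in by_rsid:
            continue
        if len(variant.ALT) != 1:
            raise InputError(f"multi-allelic record for {rsid}")
        snp = by_rsid[rsid]
        ref, alt = variant.REF, variant.ALT[0]
        if {ref, alt} != {snp.effect_allele, snp.other_allele}:
            raise InputError(
                f"allele mismatch for {rsid}: VCF {ref}/{alt} vs panel "
                f"{snp.effect_allele}/{snp.other_allele}"
            )
        alt_counts = np.full(len(samples), np.nan)
        for i, gt in enumerate(variant.genotypes):
            alleles = gt[:-1]  # last entry is the phased flag
            if any(a < 0 for a in alleles):
                continue
            alt_counts[i] = float(sum(1 for a in alleles if a > 0))
        if alt == snp.effect_allele:
            columns[rsid] = alt_counts
        else:
            columns[rsid] = 2.0 - alt_counts
    vcf.close()
    absent = [rs for rs in panel.rsids if rs not in columns]
    if absent:
        raise InputError(f"VCF missing panel SNPs: {absent}")
    dosage = np.column_stack([columns[rs] for rs in panel.rsids])
    return GenotypeMatrix(dosage, samples, panel.rsids)


def read_genotypes(path, panel: SNPPanel) -> GenotypeMatrix:
    """Dispatch on file extension: ``.vcf`` -> VCF reader, else dosage CSV."""
    if str(path).endswith((".vcf", ".vcf.gz")):
        return read_vcf(path, panel)
    return read_dosage_csv(path, panel)


def write_vcf(genotypes: GenotypeMatrix, panel: SNPPanel, path) -> None:
    """Write hard genotypes as a minimal VCF 4.2 with a GT-only FORMAT.

    The effect allele is written as ALT and the other allele as REF, so a
    round trip through :func:`read_vcf` reproduces the dosage matrix exactly.
    Missing calls become ``./.``.  Positions are synthetic 1-based indices:
    the panel is rsid-keyed and carries no genome coordinates.
    """
    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    lines = ["##fileformat=VCFv4.2", '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    lines.append("##contig=<ID=1>")
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header += genotypes.participants
    lines.append("\t".join(header))
    for j, row in enumerate(panel.table.itertuples()):
        fields = ["1", str(j + 1), row.rsid, row.other_allele, row.effect_allele,
                  ".", "PASS", ".", "GT"]
        col = genotypes.dosage[:, j]
        fields += [MISSING_GT if np.isnan(d) else gt_code[d] for d in col]
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_dosage_csv(genotypes: GenotypeMatrix, path) -> None:
    """Write the dosage matrix as CSV (empty cell = missing)."""
    frame = genotypes.to_frame()
    # integer-style formatting keeps the file diff-stable across runs
    frame.to_csv(path, float_format="%.0f", index_label="id")
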