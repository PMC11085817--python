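"""SNP weight panels.

A panel lists the variants entering the weighted genetic risk score: for each
SNP its rsID, gene label, effect (risk) allele, other allele, beta weight and
optionally the allele frequency expected in the study population.  Betas are
per-effect-allele weights; the GRS is the dosage-weighted sum over the panel.

Panels are user-supplied TSV files.  A default eight-SNP obesity panel is
bundled for simulation and examples; its weights are synthetic placeholders,
NOT literature effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

PANEL_COLUMNS = ["rsid", "gene", "effect_allele", "other_allele", "beta"]

_BASES = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class SNPPanel:
    """Per-SNP metadata for GRS construction.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``rsid, gene, effect_allele, other_allele, beta`` and
        optionally ``expected_maf``.  rsIDs must be unique, alleles distinct
        single bases, betas finite.

    Notes
    -----
    If a supplied beta is negative the counted allele is flipped at load time
    (effect and other alleles swapped, beta negated) so every weight is
    non-negative and "risk allele" semantics hold; the GRS direction then
    always points toward higher predicted BMI.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in PANEL_COLUMNS if c not in t.columns]
        if missing:
            raise InputError(f"panel missing columns: {missing}")
        if t["rsid"].duplicated().any():
            dup = t.loc[t["rsid"].duplicated(), "rsid"].tolist()
            raise InputError(f"duplicate rsids in panel: {dup}")
        if (t["effect_allele"] == t["other_allele"]).any():
            bad = t.loc[t["effect_allele"] == t["other_allele"], "rsid"].tolist()
            raise InputError(f"effect allele equals other allele for: {bad}")
        if not np.isfinite(t["beta"].to_numpy(dtype=float)).all():
            raise InputError("non-finite beta weight in panel")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SNPPanel":
        """Build a panel from a DataFrame, orienting negative betas."""
        t = frame.copy().reset_index(drop=True)
        neg = t["beta"] < 0
        if neg.any():
            ea = t.loc[neg, "effect_allele"].copy()
            t.loc[neg, "effect_allele"] = t.loc[neg, "other_allele"]
            t.loc[neg, "other_allele"] = ea
            t.loc[neg, "beta"] = -t.loc[neg, "beta"]
        return cls(t)

    @classmethod
    def from_tsv(cls, path) -> "SNPPanel":
        """Read a panel TSV (columns: rsid, gene, effect_allele, other_allele,
        beta[, expected_maf])."""
        frame = pd.read_csv(path, sep="\t", dtype={"rsid": str, "gene": str})
        return cls.from_frame(frame)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    # -- convenience accessors -------------------------------------------
    @property
    def rsids(self) -> list[str]:
        return self.table["rsid"].tolist()

    @property
    def betas(self) -> np.ndarray:
        return self.table["beta"].to_numpy(dtype=float)

    @property
    def expected_mafs(self) -> np.ndarray | None:
        if "expected_maf" in self.table.columns:
            return self.table["expected_maf"].to_numpy(dtype=float)
        return None

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, rsids) -> "SNPPanel":
        """Panel restricted to ``rsids``, preserving panel order."""
        keep = self.table["rsid"].isin(set(rsids))
        return SNPPanel(self.table.loc[keep].reset_index(drop=True))


def default_panel() -> SNPPanel:
    """The bundled eight-SNP obesity panel.

    Allele frequencies are plausible for a European-ancestry adult cohort;
    the beta weights are synthetic placeholders chosen for simulation, not
    published GWAS effect sizes.  Real analyses must supply their own panel
    TSV.  The two rsID spellings of the TMEM18 variant seen in the field
    (rs18939583 / rs939583) are not reconciled here: the panel carries
    whatever rsid the user supplies, and the default uses rs939583.
    """
    rows = [
        # rsid, gene, effect, other, beta (synthetic), expected_maf
        ("rs939583", "TMEM18", "C", "T", 0.13, 0.17),
        ("rs4994", "ADRB3", "C", "T", 0.10, 0.12),
        ("rs9939609", "FTO", "A", "T", 0.25, 0.41),
        ("rs2331841", "MC4R", "A", "G", 0.16, 0.24),
        ("rs10182181", "ADCY3", "G", "A", 0.14, 0.45),
        ("rs925946", "BDNF", "T", "G", 0.12, 0.28),
        ("rs11672660", "GIPR", "C", "T", 0.15, 0.22),
        ("rs6265", "BDNF", "T", "C", 0.17, 0.18),
    ]
    frame = pd.DataFrame(
        rows,
        columns=["rsid", "gene", "effect_allele", "other_allele", "beta", "expected_maf"],
    )
    return SNPPanel.from_frame(frame)
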