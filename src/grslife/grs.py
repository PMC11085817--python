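"""Weighted genetic risk score and quartile stratification.

The score is the dosage-weighted sum over the panel,

    GRS_i = sum_j dosage_ij * beta_j,

with dosage the count (0, 1, 2) of each SNP's risk allele and beta its
weight.  Participants are stratified into quartiles at the 25th/50th/75th
percentiles of the full scored cohort (linear-interpolation percentiles);
boundary values fall into the lower quartile, and quartiles are fixed once
cohort-wide — never recomputed inside lifestyle strata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .genotypes import GenotypeMatrix
from .panel import SNPPanel

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")


@dataclass
class GRSResult:
    """Per-participant weighted score, quartile label and the cutpoints used.

    ``scores`` has columns ``grs`` and (after :func:`assign_quartiles`)
    ``quartile``; the index is the participant id.
    """

    scores: pd.DataFrame = field(repr=False)
    cutpoints: tuple | None = None

    @property
    def grs(self) -> pd.Series:
        return self.scores["grs"]

    @property
    def quartile(self) -> pd.Series:
        if "quartile" not in self.scores.columns:
            raise InputError("quartiles not assigned yet")
        return self.scores["quartile"]

    def to_tsv(self, path) -> None:
        self.scores.to_csv(path, sep="\t", index_label="id", float_format="%.10g")


def compute_grs(genotypes: GenotypeMatrix, panel: SNPPanel) -> GRSResult:
    """Weighted score per participant.

    Requires complete dosages: participants with missing panel calls must be
    dropped (or imputed) upstream — a missing dosage here is a policy
    violation and raises :class:`InputError`.
    """
    if genotypes.missing_mask.any():
        n_bad = int(genotypes.missing_mask.any(axis=1).sum())
        raise InputError(
            f"{n_bad} participants reach scoring with missing dosages; "
            "apply the missingness policy first"
        )
    if genotypes.rsids != panel.rsids:
        raise InputError("genotype columns do not match panel order")
    grs = genotypes.dosage @ panel.betas
    scores = pd.DataFrame({"grs": grs}, index=pd.Index(genotypes.participants, name="id"))
    return GRSResult(scores=scores)


def assign_quartiles(result: GRSResult) -> GRSResult:
    """Assign Q1-Q4 labels at the 25th/50th/75th percentile cutpoints.

    Boundary rule: Q1 if grs <= c25, Q2 if c25 < grs <= c50, Q3 if
    c50 < grs <= c75, else Q4 — ties at a cutpoint all land in the lower
    quartile.  Raises on fewer than 4 participants or a degenerate
    (constant) score distribution.
    """
    grs = result.grs.to_numpy(dtype=float)
    if len(grs) < 4:
        raise InputError("need at least 4 scored participants for quartiles")
    if np.ptp(grs) == 0:
        raise InputError("degenerate score distribution: all scores identical")
    c25, c50, c75 = np.percentile(grs, [25, 50, 75])
    labels = np.select(
        [grs <= c25, grs <= c50, grs <= c75],
        ["Q1", "Q2", "Q3"],
        default="Q4",
    )
    scores = result.scores.copy()
    scores["quartile"] = pd.Categorical(labels, categories=list(QUARTILE_LABELS))
    return GRSResult(scores=scores, cutpoints=(float(c25), float(c50), float(c75)))
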