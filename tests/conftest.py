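import numpy as np
import pandas as pd
import pytest

from grslife import (
    GenotypeMatrix,
    PhenotypeTable,
    SimConfig,
    SNPPanel,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort under the default study conditions."""
    return simulate_cohort(SimConfig(seed=20240426))


@pytest.fixture(scope="session")
def small_cohort():
    """A 1500-participant cohort for quick end-to-end checks."""
    return simulate_cohort(SimConfig(n_participants=1500, seed=42))


@pytest.fixture()
def tiny_panel():
    frame = pd.DataFrame({
        "rsid": ["rs1", "rs2"],
        "gene": ["G1", "G2"],
        "effect_allele": ["A", "C"],
        "other_allele": ["G", "T"],
        "beta": [0.30, 0.15],
    })
    return SNPPanel.from_frame(frame)


def make_phenotypes(n, rng=None, ids=None, **overrides):
    """Minimal valid phenotype table for unit tests."""
    rng = rng or np.random.default_rng(0)
    data = pd.DataFrame({
        "id": ids if ids is not None else [f"P{i:04d}" for i in range(n)],
        "height_cm": np.full(n, 170.0),
        "weight_kg": rng.normal(88.0, 18.0, n).clip(45, 180),
        "age": rng.normal(55.0, 15.0, n).clip(18, 95).round(1),
        "sex": rng.choice(["female", "male"], n, p=[0.7, 0.3]),
        "t2dm": rng.binomial(1, 0.08, n),
        "pa_min_week": rng.integers(0, 400, n).astype(float),
        "ehs_score": rng.integers(0, 33, n).astype(float),
        "ssb_cups_day": rng.binomial(1, 0.12, n) * rng.integers(1, 4, n),
        "wine_drinks_week": rng.binomial(1, 0.24, n) * rng.integers(1, 4, n),
    })
    for key, value in overrides.items():
        data[key] = value
    return PhenotypeTable(data)


def make_genotypes(dosage, ids=None, rsids=None):
    dosage = np.asarray(dosage, dtype=float)
    ids = ids or [f"P{i:04d}" for i in range(dosage.shape[0])]
    rsids = rsids or [f"rs{j + 1}" for j in range(dosage.shape[1])]
    return GenotypeMatrix(dosage, ids, rsids)
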