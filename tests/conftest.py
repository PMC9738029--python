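import numpy as np
import pandas as pd
import pytest

from snpsetarch.io import GenotypeMatrix, PhenotypeTable, default_snp_meta
from snpsetarch.simulate import CohortConfig, PlantedSet, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_genotypes(dosages, missing=None, snp_ids=None, subject_ids=None,
                   meta=None):
    """Small helper to build a GenotypeMatrix from a plain array."""
    dosages = np.asarray(dosages, dtype=np.int8)
    m, n = dosages.shape
    if missing is None:
        missing = np.zeros((m, n), dtype=bool)
    if snp_ids is None:
        snp_ids = [f"snp{i:04d}" for i in range(m)]
    if subject_ids is None:
        subject_ids = [f"S{j:05d}" for j in range(n)]
    if meta is None:
        meta = default_snp_meta(snp_ids)
    return GenotypeMatrix(dosages, np.asarray(missing, bool), meta,
                          subject_ids)


def make_phenotypes(chd, t2d, subject_ids=None, seed=0):
    rng = np.random.default_rng(seed)
    n = len(chd)
    if subject_ids is None:
        subject_ids = [f"S{j:05d}" for j in range(n)]
    return PhenotypeTable(pd.DataFrame({
        "subject_id": subject_ids,
        "chd": list(chd),
        "t2d": list(t2d),
        "age": rng.uniform(45, 80, n),
        "sex": rng.integers(0, 2, n),
        "bmi": rng.normal(25, 3, n),
    }))


@pytest.fixture(scope="session")
def planted_cohort():
    """120-subject cohort with two disjoint planted biclusters."""
    sets = [
        PlantedSet(list(range(0, 12)), list(range(0, 25)), 2, 0.8, "CHD"),
        PlantedSet(list(range(12, 24)), list(range(25, 50)), 2, 0.8, "T2D"),
    ]
    cfg = CohortConfig(n_subjects=120, n_snps_chd=30, n_snps_t2d=30,
                       pattern_counts=(20, 30, 30, 40), planted_sets=sets,
                       maf_range=(0.05, 0.2), missing_rate=0.0, seed=11)
    g, pheno, truth = simulate_cohort(cfg)
    return g, pheno, truth


@pytest.fixture(scope="session")
def paper_scale_cohort():
    """Null cohort with the discovery sample's printed dimensions."""
    cfg = CohortConfig(seed=42, missing_rate=0.01)
    g, pheno, truth = simulate_cohort(cfg)
    return g, pheno, truth
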