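from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/helpers.py

from egoddn.io import PhenotypeInfo, SummaryStatRecord
from egoddn.network import build_full_ddn
from egoddn.preprocess import DiseaseSnpMatrix


@pytest.fixture(scope="session")
def reference_runs():
    """Ten seeded end-to-end runs at the reference study conditions.

    Shared session-wide because both the network-comparison and the
    stratification-recovery checks consume the same simulated cohorts.
    """
    from egoddn.reference import run_reference_seeds

    return run_reference_seeds(list(range(10)))


@pytest.fixture
def fig1b_matrix() -> DiseaseSnpMatrix:
    """Six-disease toy: D2..D6 each share SNPs with D1, D6 sharing the most.

    Shared-with-D1 counts: D2:1, D3:4, D4:1, D5:2, D6:5; each disease also
    carries private SNPs.
    """
    phecodes = [f"D{i}" for i in range(1, 7)]
    snps = [f"s{j:02d}" for j in range(20)]
    assoc = np.zeros((6, 20), dtype=np.int8)
    # D1's support: s00..s12; each alter shares a disjoint slice of it
    assoc[0, 0:13] = 1
    assoc[1, [0, 13, 14]] = 1                    # D2 shares s00
    assoc[2, [1, 2, 3, 4, 15]] = 1               # D3 shares 4
    assoc[3, [5, 16, 17]] = 1                    # D4 shares 1
    assoc[4, [6, 7, 18]] = 1                     # D5 shares 2
    assoc[5, [8, 9, 10, 11, 12, 19]] = 1         # D6 shares 5 (the most)
    return DiseaseSnpMatrix(phecodes, snps, assoc)


@pytest.fixture
def fig1b_ddn(fig1b_matrix):
    phenos = [
        PhenotypeInfo(p, name=p, category="test", sex_specific="none")
        for p in fig1b_matrix.phecodes
    ]
    return build_full_ddn(fig1b_matrix, phenos)


@pytest.fixture
def boundary_records() -> tuple[list[SummaryStatRecord], list[PhenotypeInfo]]:
    """Twelve records covering every filter boundary, with hand-derived survivors."""

    def rec(phecode, snp, p, maf, cases):
        return SummaryStatRecord(phecode, snp, "1", 1000, p, maf, cases)

    records = [
        rec("642", "s1", 1e-4, 0.05, 300),     # kept: p at the boundary
        rec("642", "s2", 1.1e-4, 0.05, 300),   # dropped: p too large
        rec("642", "s3", 1e-5, 0.01, 300),     # kept: MAF at the boundary
        rec("642", "s4", 1e-5, 0.009, 300),    # dropped: MAF below
        rec("642", "s5", 1e-5, 0.05, 200),     # kept: cases at the boundary
        rec("642", "s6", 1e-5, 0.05, 199),     # dropped: too few cases
        rec("642.1", "s1", 1e-6, 0.1, 500),    # kept: tenths PheCode allowed
        rec("642.11", "s1", 1e-6, 0.1, 500),   # dropped: hundredths PheCode
        rec("185", "s1", 1e-6, 0.1, 500),      # dropped: male-specific phenotype
        rec("250", "s2", 1e-6, 0.2, 400),      # kept
        rec("250", "s3", 0.5, 0.2, 400),       # dropped: p
        rec("642", "s7", 5e-5, 0.25, 250),     # kept
    ]
    phenos = [
        PhenotypeInfo("642", "hypertension in pregnancy", "pregnancy complications"),
        PhenotypeInfo("642.1", "preeclampsia and eclampsia", "pregnancy complications"),
        PhenotypeInfo("642.11", "preeclampsia subtype", "pregnancy complications"),
        PhenotypeInfo("185", "prostate cancer", "neoplasms", "male"),
        PhenotypeInfo("250", "diabetes mellitus", "endocrine/metabolic"),
    ]
    return records, phenos


EXPECTED_SURVIVORS = {
    ("642", "s1"),
    ("642", "s3"),
    ("642", "s5"),
    ("642.1", "s1"),
    ("250", "s2"),
    ("642", "s7"),
}
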