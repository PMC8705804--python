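"""Association filtering, LD pruning, and disease-SNP matrix semantics."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from egoddn.io import GenotypeMatrix, PhenotypeInfo, SummaryStatRecord
from egoddn.preprocess import (
    DiseaseSnpMatrix,
    FilterConfig,
    build_matrix,
    filter_associations,
    is_hundredths_phecode,
    ld_prune,
)

from conftest import EXPECTED_SURVIVORS


def rec(phecode="642", snp="s1", chrom="1", pos=1000, p=1e-5, maf=0.1, cases=300):
    return SummaryStatRecord(phecode, snp, chrom, pos, p, maf, cases)


def test_boundary_fixture_survivors(boundary_records):
    records, phenos = boundary_records
    kept = filter_associations(records, phenos)
    assert {(r.phecode, r.snp_id) for r in kept} == EXPECTED_SURVIVORS


@pytest.mark.parametrize(
    "phecode,expected",
    [("642", False), ("642.1", False), ("642.11", True), ("642.10", True), ("185", False)],
)
def test_hundredths_phecode_detection(phecode, expected):
    assert is_hundredths_phecode(phecode) is expected


def test_male_specific_phenotype_dropped_wholesale(boundary_records):
    records, phenos = boundary_records
    kept = filter_associations(records, phenos)
    assert all(r.phecode != "185" for r in kept)


def test_missing_phenotype_metadata_errors(boundary_records):
    records, phenos = boundary_records
    with pytest.raises(KeyError, match="999"):
        filter_associations(records + [rec(phecode="999")], phenos)


def test_filter_order_independence(boundary_records):
    """Applying the p/MAF/case thresholds in any order keeps the same set."""
    records, phenos = boundary_records
    base = FilterConfig()
    loose = {
        "p": FilterConfig(p_max=1.0, maf_min=base.maf_min, min_cases=base.min_cases),
        "maf": FilterConfig(p_max=base.p_max, maf_min=0.0001, min_cases=base.min_cases),
        "cases": FilterConfig(p_max=base.p_max, maf_min=base.maf_min, min_cases=0),
    }
    expected = {(r.phecode, r.snp_id) for r in filter_associations(records, phenos, base)}
    for order in itertools.permutations(["p", "maf", "cases"]):
        staged = records
        for stage in order:
            # each stage applies only one threshold (others loosened)
            cfgs = {k: v for k, v in loose.items() if k != stage}
            cfg = FilterConfig(
                p_max=base.p_max if stage == "p" else 1.0,
                maf_min=base.maf_min if stage == "maf" else 0.0001,
                min_cases=base.min_cases if stage == "cases" else 0,
            )
            staged = filter_associations(staged, phenos, cfg)
        assert {(r.phecode, r.snp_id) for r in staged} == expected


def test_loosening_p_max_is_monotone(boundary_records):
    records, phenos = boundary_records
    tight = filter_associations(records, phenos, FilterConfig(p_max=1e-6))
    loose = filter_associations(records, phenos, FilterConfig(p_max=1e-3))
    assert {(r.phecode, r.snp_id) for r in tight} <= {(r.phecode, r.snp_id) for r in loose}


# ---------------------------------------------------------------------------
# LD pruning


def _genotypes(columns: dict[str, np.ndarray]) -> GenotypeMatrix:
    snps = list(columns)
    n = len(next(iter(columns.values())))
    return GenotypeMatrix(
        [f"p{i}" for i in range(n)], snps, np.column_stack([columns[s] for s in snps])
    )


def test_correlated_pair_in_window_keeps_smaller_p():
    base = np.array([0, 0, 1, 1, 2, 2, 0, 1, 2, 0] * 3)
    partner = base.copy()
    partner[[0, 4, 8, 12]] = [2, 0, 0, 2]  # correlated but not identical
    geno = _genotypes({"a": base, "b": partner})
    r2 = np.corrcoef(base, partner)[0, 1] ** 2
    assert 0.2 < r2 < 1.0
    records = [
        rec(snp="a", pos=100_000, p=1e-8),
        rec(snp="b", pos=200_000, p=1e-5),  # 100 kb apart, inside the window
    ]
    kept = ld_prune(records, geno)
    assert [r.snp_id for r in kept] == ["a"]


def test_correlated_pair_outside_window_both_kept():
    base = np.array([0, 1, 2, 0, 1, 2, 1, 0, 2, 1] * 3)
    geno = _genotypes({"a": base, "b": base})  # R^2 = 1
    records = [
        rec(snp="a", pos=100_000, p=1e-8),
        rec(snp="b", pos=400_000, p=1e-5),  # 300 kb apart, outside 250 kb
    ]
    kept = ld_prune(records, geno)
    assert {r.snp_id for r in kept} == {"a", "b"}


def test_uncorrelated_snps_all_kept():
    rng = np.random.default_rng(0)
    # orthogonal dosage patterns by construction
    cols = {
        "a": np.array([0, 2] * 10),
        "b": np.array([0, 0, 2, 2] * 5),
        "c": np.array([0, 0, 0, 0, 2, 2, 2, 2] * 2 + [0, 0, 2, 2]),
    }
    geno = _genotypes(cols)
    records = [rec(snp=s, pos=100_000 + i * 50_000, p=1e-5) for i, s in enumerate(cols)]
    for a, b in itertools.combinations(cols, 2):
        assert abs(np.corrcoef(cols[a], cols[b])[0, 1]) < 0.45
    cfg = FilterConfig(ld_r2_max=0.21)
    assert len(ld_prune(records, geno, cfg)) == 3


def test_pruning_is_per_phenotype():
    base = np.array([0, 1, 2, 0, 1, 2, 1, 0, 2, 1] * 3)
    geno = _genotypes({"a": base, "b": base})
    records = [
        rec(phecode="642", snp="a", pos=100_000, p=1e-8),
        rec(phecode="642", snp="b", pos=150_000, p=1e-5),
        rec(phecode="250", snp="b", pos=150_000, p=1e-6),
    ]
    kept = ld_prune(records, geno)
    # 642 loses b to a; 250 has only b, keeps it
    assert {(r.phecode, r.snp_id) for r in kept} == {("642", "a"), ("250", "b")}


def test_missing_snp_in_genotypes_errors():
    geno = _genotypes({"a": np.array([0, 1, 2, 0])})
    with pytest.raises(KeyError, match="'b'"):
        ld_prune([rec(snp="a"), rec(snp="b", pos=2000)], geno)


def test_pruned_set_is_maximal_under_greedy_rule():
    """Every removed SNP conflicts (R^2 > max) with a kept SNP in its window."""
    rng = np.random.default_rng(42)
    n, m = 120, 30
    base = rng.binomial(2, 0.3, size=(n, m))
    # induce LD by copying neighbours with noise
    for j in range(1, m):
        mask = rng.random(n) < 0.7
        base[mask, j] = base[mask, j - 1]
    snps = [f"s{j:02d}" for j in range(m)]
    geno = GenotypeMatrix([f"p{i}" for i in range(n)], snps, base)
    records = [
        rec(snp=s, pos=10_000 * (j + 1), p=float(rng.uniform(1e-9, 1e-4)))
        for j, s in enumerate(snps)
    ]
    cfg = FilterConfig(ld_r2_max=0.2, ld_window_kb=50)
    kept = ld_prune(records, geno, cfg)
    kept_ids = {r.snp_id for r in kept}
    removed = [r for r in records if r.snp_id not in kept_ids]
    for r in removed:
        conflicts = False
        for k in kept:
            if abs(k.pos - r.pos) <= cfg.ld_window_kb * 1000:
                r2 = np.corrcoef(geno.column(r.snp_id), geno.column(k.snp_id))[0, 1] ** 2
                if r2 > cfg.ld_r2_max:
                    conflicts = True
                    break
        assert conflicts, f"{r.snp_id} was removed without a conflicting kept SNP"


# ---------------------------------------------------------------------------
# matrix construction


def test_matrix_count_conservation():
    records = [
        rec(phecode="A", snp="s1"),
        rec(phecode="A", snp="s2"),
        rec(phecode="B", snp="s2"),
        rec(phecode="B", snp="s3"),
    ]
    m = build_matrix(records)
    assert m.assoc.sum() == 4
    assert m.phecodes == ["A", "B"]
    assert m.snp_ids == ["s1", "s2", "s3"]


def test_matrix_duplicates_collapse_to_single_one():
    m = build_matrix([rec(phecode="A", snp="s1"), rec(phecode="A", snp="s1")])
    assert m.assoc.sum() == 1


def test_matrix_empty_input_errors():
    with pytest.raises(ValueError, match="no associations survive"):
        build_matrix([])


def test_fully_filtered_phenotype_absent_from_matrix(boundary_records):
    records, phenos = boundary_records
    kept = filter_associations(records, phenos)
    m = build_matrix(kept)
    assert "185" not in m.phecodes
    assert "642.11" not in m.phecodes


def test_matrix_rejects_all_zero_rows():
    with pytest.raises(ValueError, match="all-zero"):
        DiseaseSnpMatrix(["A", "B"], ["s1"], np.array([[1], [0]]))


def test_recovered_snp_sets_match_planted_causal_sets():
    """Full preprocessing recovers planted causal SNPs with recall >= 0.8."""
    from egoddn.preprocess import build_matrix, filter_associations, ld_prune
    from egoddn.simulate import SimulationConfig, association_scan, simulate_cohort

    recalls = []
    for seed in range(10):
        config = SimulationConfig(
            n_individuals=5000,
            n_snps=100,
            n_diseases=5,
            causal_per_disease=10,
            effect_size=0.8,
            prevalence=0.2,
            maf_low=0.05,
            maf_high=0.5,
            seed=seed,
        )
        cohort = simulate_cohort(config)
        records = association_scan(cohort)
        phenos = cohort.phenotype_info()
        kept = ld_prune(filter_associations(records, phenos), cohort.genotypes)
        matrix = build_matrix(kept)
        for phecode, truth in cohort.causal_sets.items():
            found = matrix.support(phecode) if phecode in matrix.phecodes else set()
            recalls.append(len(found & truth) / len(truth))
    assert np.mean(recalls) >= 0.8
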