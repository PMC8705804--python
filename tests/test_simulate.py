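"""Synthetic cohort generator: planted structure, calibration, determinism."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from egoddn.comorbidity import phi_from_counts
from egoddn.simulate import (
    PleiotropyBlock,
    SimulationConfig,
    allelic_chi2,
    association_scan,
    emit_diagnoses,
    phecode_of,
    simulate_cohort,
)


def small_config(**kwargs) -> SimulationConfig:
    defaults = dict(
        n_individuals=400,
        n_snps=40,
        n_diseases=3,
        causal_per_disease=8,
        effect_size=0.5,
        prevalence=0.3,
        maf_low=0.1,
        maf_high=0.5,
        seed=0,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


def _status_phi(cohort, i: int, j: int) -> tuple[float, float]:
    si = cohort.disease_status[:, i].astype(bool)
    sj = cohort.disease_status[:, j].astype(bool)
    phi, pvalue, _ = phi_from_counts(
        int((si & sj).sum()), int(si.sum()), int(sj.sum()), len(si)
    )
    return phi, pvalue


# ---------------------------------------------------------------------------
# config validation


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(n_individuals=1),
        dict(causal_per_disease=100),
        dict(prevalence=0.0),
        dict(prevalence=1.0),
        dict(maf_low=0.0),
        dict(maf_low=0.4, maf_high=0.2),
    ],
)
def test_invalid_configs_rejected_before_sampling(kwargs):
    with pytest.raises(ValueError):
        small_config(**kwargs)


def test_block_index_out_of_range_rejected():
    with pytest.raises(ValueError, match="out of range"):
        small_config(pleiotropy_blocks=(PleiotropyBlock((0, 9), 2),))


def test_block_budget_exceeding_causal_count_rejected():
    with pytest.raises(ValueError, match="exceed"):
        small_config(pleiotropy_blocks=(PleiotropyBlock((0, 1), 5), PleiotropyBlock((0, 2), 5)))


# ---------------------------------------------------------------------------
# cohort structure


def test_same_seed_reproduces_cohort_exactly():
    c1 = simulate_cohort(small_config())
    c2 = simulate_cohort(small_config())
    assert (c1.genotypes.dosages == c2.genotypes.dosages).all()
    assert (c1.disease_status == c2.disease_status).all()
    assert c1.causal_sets == c2.causal_sets
    r1 = association_scan(c1)
    r2 = association_scan(c2)
    assert r1 == r2
    assert emit_diagnoses(c1, seed=5) == emit_diagnoses(c2, seed=5)


def test_blocks_share_exactly_the_configured_snps():
    config = small_config(
        pleiotropy_blocks=(PleiotropyBlock((0, 1), 5), PleiotropyBlock((1, 2), 3))
    )
    cohort = simulate_cohort(config)
    sets = cohort.causal_sets
    assert all(len(s) == config.causal_per_disease for s in sets.values())
    assert len(sets[phecode_of(0)] & sets[phecode_of(1)]) == 5
    assert len(sets[phecode_of(1)] & sets[phecode_of(2)]) == 3
    assert len(sets[phecode_of(0)] & sets[phecode_of(2)]) == 0


def test_antagonistic_block_flips_signs():
    config = small_config(
        pleiotropy_blocks=(PleiotropyBlock((0, 1), 4, signs=(1, -1)),)
    )
    cohort = simulate_cohort(config)
    shared = cohort.causal_sets[phecode_of(0)] & cohort.causal_sets[phecode_of(1)]
    assert all(cohort.causal_signs[phecode_of(0)][s] == 1 for s in shared)
    assert all(cohort.causal_signs[phecode_of(1)][s] == -1 for s in shared)


def test_realized_prevalence_near_target():
    config = small_config(n_individuals=20_000, prevalence=0.2, seed=3)
    cohort = simulate_cohort(config)
    prev = cohort.disease_status.mean(axis=0)
    assert np.abs(prev - 0.2).max() < 0.02


def test_no_genetic_effect_gives_independent_diseases():
    """effect_size=0: phi centred on 0 over 50 replicate pairs at n=2000."""
    phis = []
    for seed in range(50):
        cohort = simulate_cohort(
            small_config(n_individuals=2000, n_diseases=2, effect_size=0.0,
                         pleiotropy_blocks=(PleiotropyBlock((0, 1), 8),), seed=seed)
        )
        phis.append(_status_phi(cohort, 0, 1)[0])
    assert abs(float(np.mean(phis))) < 0.02


def test_full_causal_overlap_produces_positive_cooccurrence():
    """Shared causal sets: phi > 0 with p < 0.05 in at least 95 of 100 seeds."""
    hits = 0
    for seed in range(100):
        cohort = simulate_cohort(
            small_config(
                n_individuals=5000,
                n_snps=20,
                n_diseases=2,
                causal_per_disease=10,
                effect_size=0.5,
                prevalence=0.2,
                pleiotropy_blocks=(PleiotropyBlock((0, 1), 10),),
                seed=seed,
            )
        )
        phi, pvalue = _status_phi(cohort, 0, 1)
        hits += phi > 0 and pvalue < 0.05
    assert hits >= 95


def test_planted_overlap_monotone_in_cooccurrence():
    """Mean phi with the ego strictly increases over overlaps {0, 5, 10}."""
    sums = np.zeros(3)
    for seed in range(25):
        cohort = simulate_cohort(
            SimulationConfig(
                n_individuals=5000,
                n_snps=60,
                n_diseases=4,
                causal_per_disease=15,
                effect_size=0.5,
                prevalence=0.2,
                maf_low=0.1,
                maf_high=0.5,
                pleiotropy_blocks=(
                    PleiotropyBlock((0, 2), 5),
                    PleiotropyBlock((0, 3), 10),
                ),
                seed=seed,
            )
        )
        for k, partner in enumerate((1, 2, 3)):  # overlaps 0, 5, 10
            sums[k] += _status_phi(cohort, 0, partner)[0]
    means = sums / 25
    assert means[0] < means[1] < means[2]


# ---------------------------------------------------------------------------
# association scan


def test_worked_allele_table_chi2():
    """[[120,80],[80,120]] -> chi2 = 16, p ~ 6.33e-5."""
    chi2, pvalue = allelic_chi2(np.array([[120, 80], [80, 120]]))
    assert chi2 == pytest.approx(16.0, abs=1e-12)
    assert pvalue == pytest.approx(6.33e-5, rel=0.01)
    oracle = stats.chi2_contingency([[120, 80], [80, 120]], correction=False)
    assert chi2 == pytest.approx(oracle.statistic, abs=1e-10)
    assert pvalue == pytest.approx(oracle.pvalue, abs=1e-10)


def test_equal_allele_frequencies_give_zero_statistic():
    chi2, pvalue = allelic_chi2(np.array([[50, 50], [150, 150]]))
    assert chi2 == 0.0
    assert pvalue == 1.0


def test_zero_margin_gives_pvalue_one():
    chi2, pvalue = allelic_chi2(np.array([[0, 100], [0, 300]]))
    assert (chi2, pvalue) == (0.0, 1.0)


def test_causal_snp_power():
    """effect 0.8, prevalence 0.3, n=4000: p <= 1e-4 in >= 90% of 50 seeds."""
    hits = 0
    for seed in range(50):
        config = small_config(
            n_individuals=4000, n_snps=10, causal_per_disease=4,
            n_diseases=1, effect_size=0.8, prevalence=0.3, seed=seed,
        )
        cohort = simulate_cohort(config)
        records = {r.snp_id: r for r in association_scan(cohort)}
        causal = sorted(cohort.causal_sets[phecode_of(0)])[0]
        hits += records[causal].pvalue <= 1e-4
    assert hits >= 45


def test_null_snp_calibration():
    """Null SNPs reject at the nominal 5% rate (within [0.03, 0.07])."""
    config = SimulationConfig(
        n_individuals=5000,
        n_snps=2100,
        n_diseases=5,
        causal_per_disease=10,
        effect_size=0.5,
        prevalence=0.3,
        maf_low=0.1,
        maf_high=0.5,
        seed=12,
    )
    cohort = simulate_cohort(config)
    records = association_scan(cohort)
    causal = {
        (p, s) for p, snps in cohort.causal_sets.items() for s in snps
    }
    null_p = [r.pvalue for r in records if (r.phecode, r.snp_id) not in causal]
    assert len(null_p) >= 10_000
    frac = float(np.mean(np.array(null_p) <= 0.05))
    assert 0.03 <= frac <= 0.07


def test_scan_skips_caseless_disease(caplog):
    import logging

    config = small_config(prevalence=0.0005, n_individuals=500, seed=1)
    cohort = simulate_cohort(config)
    assert (cohort.disease_status.sum(axis=0) == 0).any()
    with caplog.at_level(logging.WARNING):
        records = association_scan(cohort)
    emitted = {r.phecode for r in records}
    empty = {
        phecode_of(d)
        for d in range(config.n_diseases)
        if cohort.disease_status[:, d].sum() == 0
    }
    assert emitted.isdisjoint(empty)
    assert "skipped" in caplog.text


def test_scan_positions_evenly_spaced():
    cohort = simulate_cohort(small_config())
    records = association_scan(cohort)
    one_disease = [r for r in records if r.phecode == phecode_of(0)]
    positions = sorted(r.pos for r in one_disease)
    assert positions[0] == cohort.config.spacing_bp
    diffs = set(np.diff(positions))
    assert diffs == {cohort.config.spacing_bp}


def test_ld_block_mode_induces_target_correlation():
    config = small_config(
        n_individuals=4000, n_snps=20, n_diseases=1, ld_block_size=2, ld_block_r2=0.5, seed=7
    )
    cohort = simulate_cohort(config)
    r2s = []
    for j in range(0, 20, 2):
        a = cohort.genotypes.dosages[:, j].astype(float)
        b = cohort.genotypes.dosages[:, j + 1].astype(float)
        r2s.append(np.corrcoef(a, b)[0, 1] ** 2)
    assert np.mean(r2s) == pytest.approx(0.5, abs=0.1)


# ---------------------------------------------------------------------------
# diagnosis emission


def test_perfect_sensitivity_specificity_reproduces_status():
    config = small_config(diagnosis_sensitivity=1.0, diagnosis_specificity=1.0)
    cohort = simulate_cohort(config)
    records = emit_diagnoses(cohort, seed=2)
    observed = {(r.person_id, r.code) for r in records}
    expected = {
        (cohort.genotypes.person_ids[i], phecode_of(d))
        for i, d in np.argwhere(cohort.disease_status == 1)
    }
    assert observed == expected


def test_zero_sensitivity_emits_no_case_records():
    config = small_config(diagnosis_sensitivity=0.0, diagnosis_specificity=1.0)
    cohort = simulate_cohort(config)
    assert emit_diagnoses(cohort, seed=2) == []


def test_emission_count_within_binomial_bounds():
    """sensitivity 0.8 over ~1000 true cases lands in the 99% interval."""
    config = small_config(
        n_individuals=4000, n_diseases=1, prevalence=0.25,
        diagnosis_sensitivity=0.8, diagnosis_specificity=1.0, seed=4,
    )
    cohort = simulate_cohort(config)
    n_cases = int(cohort.disease_status.sum())
    emitted = len(emit_diagnoses(cohort, seed=9))
    lo, hi = stats.binom.ppf([0.005, 0.995], n_cases, 0.8)
    assert lo <= emitted <= hi
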