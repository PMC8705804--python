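"""Comorbidity ground truth from diagnosis records via the phi-correlation.

For a pair of diseases (i, j) in a cohort of N persons, with P_i and P_j
persons ever diagnosed with each disease and C_ij persons diagnosed with both,

    phi_ij = (C_ij * N - P_i * P_j) / sqrt(P_i * P_j * (N - P_i) * (N - P_j)),

the Pearson correlation of the two person-level binary disease indicators.
Significance uses the classical identity chi-squared = N * phi^2 on 1 df (the
2x2 Pearson statistic without continuity correction); Fisher's exact test is
available for small counts.  A pair is a true comorbidity iff phi > 0,
p < 0.05 and C_ij > 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import DiagnosisRecord, IcdPhecodeMapEntry
from .network import EgoNetwork

log = logging.getLogger(__name__)

PHI_SIGNIFICANCE = 0.05


@dataclass(frozen=True)
class ComorbidityStat:
    """Phi-correlation between two diseases with its co-occurrence counts."""

    phecode_i: str
    phecode_j: str
    c_ij: int
    p_i: int
    p_j: int
    n: int
    phi: float
    pvalue: float
    degenerate: bool = False

    @property
    def is_comorbid(self) -> bool:
        return self.phi > 0 and self.pvalue < PHI_SIGNIFICANCE and self.c_ij > 0


def map_diagnoses_to_phecodes(
    records: list[DiagnosisRecord], mapping: list[IcdPhecodeMapEntry]
) -> list[DiagnosisRecord]:
    """Map ICD diagnosis records to PheCodes.

    Each ICD record expands to every PheCode it maps to; records already in
    the PheCode system pass through.  Unmapped ICD codes are dropped with a
    logged count and the output is deduplicated on (person_id, phecode),
    sorted for determinism.
    """
    if not mapping:
        raise ValueError("empty ICD->PheCode mapping")
    lookup: dict[tuple[str, int], list[str]] = {}
    for entry in mapping:
        lookup.setdefault((entry.icd_code, entry.icd_version), []).append(entry.phecode)

    seen: set[tuple[str, str]] = set()
    unmapped = 0
    for rec in records:
        if rec.code_system == "PheCode":
            seen.add((rec.person_id, rec.code))
            continue
        version = 9 if rec.code_system == "ICD9" else 10
        phecodes = lookup.get((rec.code, version))
        if not phecodes:
            unmapped += 1
            continue
        for code in phecodes:
            seen.add((rec.person_id, code))
    if unmapped:
        log.warning("dropped %d diagnosis record(s) with unmapped ICD codes", unmapped)
    return [
        DiagnosisRecord(person_id=p, code=c, code_system="PheCode")
        for p, c in sorted(seen)
    ]


def phi_from_counts(
    c_ij: int, p_i: int, p_j: int, n: int, use_fisher: bool = False
) -> tuple[float, float, bool]:
    """Phi and its p-value from 2x2 co-occurrence counts.

    Returns (phi, pvalue, degenerate); the pair is degenerate when either
    disease is absent from, or universal in, the cohort, in which case
    phi = 0 and pvalue = 1.
    """
    if not (0 <= c_ij <= min(p_i, p_j)):
        raise ValueError(f"C_ij={c_ij} inconsistent with P_i={p_i}, P_j={p_j}")
    if max(p_i, p_j) > n:
        raise ValueError(f"P_i={p_i}, P_j={p_j} exceed cohort size N={n}")
    denom = float(p_i) * p_j * (n - p_i) * (n - p_j)
    if denom == 0:
        return 0.0, 1.0, True
    phi = (c_ij * float(n) - float(p_i) * p_j) / np.sqrt(denom)
    if use_fisher:
        table = [[c_ij, p_i - c_ij], [p_j - c_ij, n - p_i - p_j + c_ij]]
        pvalue = float(stats.fisher_exact(table)[1])
    else:
        pvalue = float(stats.chi2.sf(n * phi * phi, df=1))
    return float(phi), pvalue, False


def _indicator_counts(
    diagnoses: list[DiagnosisRecord], pair: tuple[str, str], cohort_ids: list[str]
) -> tuple[int, int, int, int]:
    cohort = set(cohort_ids)
    if len(cohort) != len(cohort_ids):
        raise ValueError("cohort_ids contains duplicates")
    have_i: set[str] = set()
    have_j: set[str] = set()
    for rec in diagnoses:
        if rec.code_system != "PheCode" or rec.person_id not in cohort:
            continue
        if rec.code == pair[0]:
            have_i.add(rec.person_id)
        elif rec.code == pair[1]:
            have_j.add(rec.person_id)
    return len(have_i & have_j), len(have_i), len(have_j), len(cohort)


def phi_correlation(
    diagnoses: list[DiagnosisRecord],
    pair: tuple[str, str],
    cohort_ids: list[str],
    use_fisher: bool = False,
) -> ComorbidityStat:
    """Phi-correlation between two diseases over a person cohort.

    Diagnoses must already be in the PheCode system (see
    :func:`map_diagnoses_to_phecodes`); persons outside ``cohort_ids`` are
    ignored, and "ever had" semantics apply (any record counts).
    """
    if pair[0] == pair[1]:
        raise ValueError(f"self-pair {pair[0]!r}")
    if len(set(cohort_ids)) < 2:
        raise ValueError("cohort must contain at least 2 persons")
    c_ij, p_i, p_j, n = _indicator_counts(diagnoses, pair, cohort_ids)
    phi, pvalue, degenerate = phi_from_counts(c_ij, p_i, p_j, n, use_fisher=use_fisher)
    return ComorbidityStat(pair[0], pair[1], c_ij, p_i, p_j, n, phi, pvalue, degenerate)


def label_alters(
    net: EgoNetwork,
    diagnoses: list[DiagnosisRecord],
    cohort_ids: list[str],
    use_fisher: bool = False,
) -> dict[str, ComorbidityStat]:
    """Phi-based comorbidity stat for every (ego, alter) pair of an ego network.

    Alters never diagnosed in the cohort still receive a stat (degenerate,
    not comorbid).
    """
    return {
        alter: phi_correlation(diagnoses, (net.ego, alter), cohort_ids, use_fisher)
        for alter in net.alters
    }
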