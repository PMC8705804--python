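"""Individual-level stratification by shared-SNP carrier status.

For a connected (ego, alter) disease pair, the shared SNP set S is the edge's
annotation.  Among persons ever diagnosed with the ego disease, a 2x2
contingency table crosses carrier status (dosage >= 1 at >= 1 SNP of S)
against diagnosis group (both diseases vs. ego only).  Independence is tested
with the Pearson chi-squared statistic on 1 df (no continuity correction by
default); the odds ratio uses the Haldane 0.5 correction when a cell is zero.
A significant test indicates that carriers of the shared variants are at
different comorbidity risk than non-carriers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import DiagnosisRecord, GenotypeMatrix
from .network import EdgeAnnotation

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Carrier status x diagnosis group among persons with the ego disease."""

    carrier_both: int
    carrier_ego_only: int
    noncarrier_both: int
    noncarrier_ego_only: int

    def __post_init__(self) -> None:
        if min(self.counts().ravel()) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty contingency table")

    def counts(self) -> np.ndarray:
        return np.array(
            [
                [self.carrier_both, self.carrier_ego_only],
                [self.noncarrier_both, self.noncarrier_ego_only],
            ],
            dtype=float,
        )

    @property
    def total(self) -> int:
        return (
            self.carrier_both
            + self.carrier_ego_only
            + self.noncarrier_both
            + self.noncarrier_ego_only
        )


@dataclass(frozen=True)
class StratificationResult:
    table: ContingencyTable2x2
    chi2: float
    pvalue: float
    odds_ratio: float
    degenerate: bool
    shared_snp_ids: tuple[str, ...]


def _diagnosed(diagnoses: list[DiagnosisRecord], code: str) -> set[str]:
    return {
        r.person_id for r in diagnoses if r.code_system == "PheCode" and r.code == code
    }


def build_contingency(
    ego: str,
    alter: str,
    shared: EdgeAnnotation,
    genotypes: GenotypeMatrix,
    diagnoses: list[DiagnosisRecord],
) -> ContingencyTable2x2:
    """Cross carrier status with comorbidity among ego-diagnosed persons.

    The population is every genotyped person ever diagnosed with the ego
    disease; a carrier holds at least one alternate allele at at least one
    SNP of the shared set.
    """
    if shared.n_shared_snps < 1:
        raise ValueError("shared SNP set is empty")
    cols = []
    for snp in shared.shared_snp_ids:
        cols.append(genotypes.column(snp))  # KeyError if absent
    dosage = np.column_stack(cols)
    carrier = dict(zip(genotypes.person_ids, (dosage >= 1).any(axis=1)))

    ego_persons = _diagnosed(diagnoses, ego) & set(genotypes.person_ids)
    if not ego_persons:
        raise ValueError("empty stratification population: no person with the ego diagnosis")
    alter_persons = _diagnosed(diagnoses, alter)

    cells = {(True, True): 0, (True, False): 0, (False, True): 0, (False, False): 0}
    for person in ego_persons:
        cells[(bool(carrier[person]), person in alter_persons)] += 1
    return ContingencyTable2x2(
        carrier_both=cells[(True, True)],
        carrier_ego_only=cells[(True, False)],
        noncarrier_both=cells[(False, True)],
        noncarrier_ego_only=cells[(False, False)],
    )


def chi2_from_table(table: ContingencyTable2x2) -> tuple[float, float, bool]:
    """Pearson chi-squared (1 df, no continuity correction) for a 2x2 table.

    Uses the closed form N (ad - bc)^2 / (r1 r2 c1 c2); a zero margin makes
    the test degenerate (chi2 = 0, p = 1).
    """
    a, b = table.carrier_both, table.carrier_ego_only
    c, d = table.noncarrier_both, table.noncarrier_ego_only
    n = table.total
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 0.0, 1.0, True
    chi2 = n * (a * d - b * c) ** 2 / float(r1 * r2 * c1 * c2)
    return float(chi2), float(stats.chi2.sf(chi2, df=1)), False


def chi_squared_test(
    table: ContingencyTable2x2,
    shared_snp_ids: tuple[str, ...] = (),
    yates: bool = False,
) -> StratificationResult:
    """Test independence of carrier status and comorbidity.

    ``yates`` applies the continuity correction |ad - bc| -> |ad - bc| - N/2
    (floored at 0).  A warning is logged when any expected cell count is
    below 5.
    """
    counts = table.counts()
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / table.total
    if not yates:
        chi2, pvalue, degenerate = chi2_from_table(table)
    else:
        a, b = table.carrier_both, table.carrier_ego_only
        c, d = table.noncarrier_both, table.noncarrier_ego_only
        n = table.total
        r1, r2, c1, c2 = a + b, c + d, a + c, b + d
        if min(r1, r2, c1, c2) == 0:
            chi2, pvalue, degenerate = 0.0, 1.0, True
        else:
            adj = max(abs(a * d - b * c) - n / 2, 0.0)
            chi2 = n * adj**2 / float(r1 * r2 * c1 * c2)
            chi2, pvalue, degenerate = float(chi2), float(stats.chi2.sf(chi2, df=1)), False
    if not degenerate and (expected < 5).any():
        log.warning("expected cell count below 5; chi-squared approximation is coarse")

    a, b = table.carrier_both, table.carrier_ego_only
    c, d = table.noncarrier_both, table.noncarrier_ego_only
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5  # Haldane correction
    odds_ratio = (a * d) / (b * c)
    return StratificationResult(
        table=table,
        chi2=chi2,
        pvalue=pvalue,
        odds_ratio=float(odds_ratio),
        degenerate=degenerate,
        shared_snp_ids=tuple(shared_snp_ids),
    )


def stratify_pair(
    ego: str,
    alter: str,
    shared: EdgeAnnotation,
    genotypes: GenotypeMatrix,
    diagnoses: list[DiagnosisRecord],
    yates: bool = False,
) -> StratificationResult:
    """Build the contingency table for an (ego, alter) pair and test it."""
    table = build_contingency(ego, alter, shared, genotypes, diagnoses)
    return chi_squared_test(table, shared_snp_ids=shared.shared_snp_ids, yates=yates)
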