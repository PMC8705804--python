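"""Association filtering, LD pruning, and the binary disease-SNP matrix.

The filtering criteria mirror the standard PheWAS pre-processing for a
variant-sharing diseasome: keep associations with p-value <= 1e-4 (inclusive),
minor allele frequency >= 0.01, at least 200 cases; drop male-specific
phenotypes (the networks target female cohorts) and PheCodes specified to the
hundredth's place (sub-sub-phenotypes, excluded for interpretability).
Surviving SNPs are LD-pruned per phenotype with a greedy keep-best-by-p sweep
(R-squared threshold within a base-pair window, PLINK-like semantics).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import GenotypeMatrix, PhenotypeInfo, SummaryStatRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for association filtering and LD pruning."""

    p_max: float = 1e-4
    maf_min: float = 0.01
    min_cases: int = 200
    ld_r2_max: float = 0.2
    ld_window_kb: int = 250
    exclude_sex: frozenset[str] = frozenset({"male"})
    exclude_hundredths_phecodes: bool = True
    ld_scope: str = "per_phenotype"  # or "global"
    ld_order: str = "pvalue"  # or "position"

    def __post_init__(self) -> None:
        if not (0 < self.p_max <= 1):
            raise ValueError(f"p_max must be in (0,1]: {self.p_max}")
        if not (0 <= self.ld_r2_max <= 1):
            raise ValueError(f"ld_r2_max must be in [0,1]: {self.ld_r2_max}")
        if self.ld_window_kb <= 0:
            raise ValueError(f"ld_window_kb must be positive: {self.ld_window_kb}")
        if not frozenset(self.exclude_sex) <= {"male", "female"}:
            raise ValueError(f"exclude_sex entries must be 'male'/'female': {self.exclude_sex}")
        if self.ld_scope not in ("per_phenotype", "global"):
            raise ValueError(f"ld_scope must be 'per_phenotype' or 'global': {self.ld_scope}")
        if self.ld_order not in ("pvalue", "position"):
            raise ValueError(f"ld_order must be 'pvalue' or 'position': {self.ld_order}")


def is_hundredths_phecode(phecode: str) -> bool:
    """True when the PheCode has two or more decimal digits (e.g. "642.11").

    PheCode strings are canonical and never zero-padded, so a plain string
    test on the decimal part is exact ("642.10" counts as hundredths).
    """
    _, _, frac = phecode.partition(".")
    return len(frac) >= 2


@dataclass
class DiseaseSnpMatrix:
    """Binary phenotype x variant association matrix.

    Row support sets are the per-disease significant-SNP sets; every row and
    column has at least one nonzero entry.
    """

    phecodes: list[str]
    snp_ids: list[str]
    assoc: np.ndarray  # disease x SNP, entries in {0,1}

    def __post_init__(self) -> None:
        self.assoc = np.asarray(self.assoc, dtype=np.int8)
        if self.assoc.shape != (len(self.phecodes), len(self.snp_ids)):
            raise ValueError("assoc shape does not match phecode/SNP lists")
        if not np.isin(self.assoc, (0, 1)).all():
            raise ValueError("assoc entries must be 0 or 1")
        if len(self.phecodes) and (self.assoc.sum(axis=1) == 0).any():
            raise ValueError("all-zero matrix row")
        if len(self.snp_ids) and (self.assoc.sum(axis=0) == 0).any():
            raise ValueError("all-zero matrix column")

    def support(self, phecode: str) -> set[str]:
        i = self.phecodes.index(phecode)
        return {self.snp_ids[j] for j in np.flatnonzero(self.assoc[i])}

    def to_pairs(self) -> list[tuple[str, str]]:
        return [
            (self.phecodes[i], self.snp_ids[j]) for i, j in np.argwhere(self.assoc == 1)
        ]


def filter_associations(
    records: list[SummaryStatRecord],
    phenos: list[PhenotypeInfo],
    cfg: FilterConfig = FilterConfig(),
) -> list[SummaryStatRecord]:
    """Apply the p-value / MAF / case-count / phenotype-level filters.

    Thresholds are inclusive (p <= p_max, maf >= maf_min, cases >= min_cases).
    Records of excluded phenotypes (sex-specific or hundredths PheCodes) are
    dropped wholesale.
    """
    info = {p.phecode: p for p in phenos}
    missing = {r.phecode for r in records if r.phecode not in info}
    if missing:
        raise KeyError(f"phecode(s) missing from phenotype info: {sorted(missing)}")

    dropped_pheno: set[str] = set()
    kept: list[SummaryStatRecord] = []
    for r in records:
        p = info[r.phecode]
        if p.sex_specific in cfg.exclude_sex or (
            cfg.exclude_hundredths_phecodes and is_hundredths_phecode(r.phecode)
        ):
            dropped_pheno.add(r.phecode)
            continue
        if r.pvalue <= cfg.p_max and r.maf >= cfg.maf_min and r.n_cases >= cfg.min_cases:
            kept.append(r)
    log.info(
        "filter_associations: %d records in, %d kept, %d phenotype(s) excluded",
        len(records),
        len(kept),
        len(dropped_pheno),
    )
    return kept


def _dosage_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (0 if either is constant)."""
    x = x.astype(float)
    y = y.astype(float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return 0.0
    return float((xc @ yc) / denom) ** 2


def _greedy_prune(
    records: list[SummaryStatRecord], genotypes: GenotypeMatrix, cfg: FilterConfig
) -> set[tuple[str, str]]:
    """Greedy sweep; returns the set of kept (phecode, snp_id) keys."""
    if cfg.ld_order == "pvalue":
        order = sorted(records, key=lambda r: (r.pvalue, r.pos, r.snp_id))
    else:
        order = sorted(records, key=lambda r: (r.chrom, r.pos, r.snp_id))
    window_bp = cfg.ld_window_kb * 1000
    kept: list[SummaryStatRecord] = []
    dosage_cache: dict[str, np.ndarray] = {}

    def dosage(snp_id: str) -> np.ndarray:
        if snp_id not in dosage_cache:
            try:
                dosage_cache[snp_id] = genotypes.column(snp_id)
            except KeyError:
                raise KeyError(f"SNP {snp_id!r} absent from genotype matrix") from None
        return dosage_cache[snp_id]

    for cand in order:
        ok = True
        for k in kept:
            if k.chrom != cand.chrom or abs(k.pos - cand.pos) > window_bp:
                continue
            if _dosage_r2(dosage(cand.snp_id), dosage(k.snp_id)) > cfg.ld_r2_max:
                ok = False
                break
        if ok:
            kept.append(cand)
    return {(r.phecode, r.snp_id) for r in kept}


def ld_prune(
    records: list[SummaryStatRecord],
    genotypes: GenotypeMatrix,
    cfg: FilterConfig = FilterConfig(),
) -> list[SummaryStatRecord]:
    """LD-prune association records; original record order is preserved.

    Per phenotype (default), SNPs are swept in ascending p-value order (ties
    broken by position); a SNP is kept iff its dosage R-squared with every
    already-kept SNP on the same chromosome within the window is <= the
    threshold.  In ``global`` scope one sweep is run over the distinct SNPs
    (best p-value per SNP) and the kept SNP set is applied to all phenotypes.
    """
    if cfg.ld_scope == "per_phenotype":
        kept_keys: set[tuple[str, str]] = set()
        by_pheno: dict[str, list[SummaryStatRecord]] = {}
        for r in records:
            by_pheno.setdefault(r.phecode, []).append(r)
        for recs in by_pheno.values():
            kept_keys |= _greedy_prune(recs, genotypes, cfg)
        out = [r for r in records if (r.phecode, r.snp_id) in kept_keys]
    else:
        best: dict[str, SummaryStatRecord] = {}
        for r in records:
            if r.snp_id not in best or r.pvalue < best[r.snp_id].pvalue:
                best[r.snp_id] = r
        kept_snps = {s for _, s in _greedy_prune(list(best.values()), genotypes, cfg)}
        out = [r for r in records if r.snp_id in kept_snps]
    log.info("ld_prune: %d records in, %d kept", len(records), len(out))
    return out


def build_matrix(records: list[SummaryStatRecord]) -> DiseaseSnpMatrix:
    """Build the binary disease-SNP matrix from surviving associations.

    Rows (phecodes) and columns (SNP ids) are sorted; duplicate records
    collapse to a single 1.
    """
    if not records:
        raise ValueError("no associations survive filtering")
    phecodes = sorted({r.phecode for r in records})
    snp_ids = sorted({r.snp_id for r in records})
    prow = {p: i for i, p in enumerate(phecodes)}
    pcol = {s: j for j, s in enumerate(snp_ids)}
    assoc = np.zeros((len(phecodes), len(snp_ids)), dtype=np.int8)
    for r in records:
        assoc[prow[r.phecode], pcol[r.snp_id]] = 1
    return DiseaseSnpMatrix(phecodes, snp_ids, assoc)
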