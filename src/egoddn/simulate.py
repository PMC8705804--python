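"""Synthetic pleiotropic cohort: genotypes, liability-threshold diseases,
diagnosis records, and per-disease association summary statistics.

The generator plants the structural assumption the pipeline exploits: disease
pairs sharing more causal variants both share significant associations (hence
an edge in the disease-disease network) and co-occur more often in the
diagnosis records.  Per SNP, a minor allele frequency is drawn uniformly and
genotypes follow Hardy-Weinberg Binomial(2, maf).  Each disease's liability is

    liability = effect_size * sum over causal SNPs of sign * z + noise,

with z the maf-standardized dosage and noise standard normal; a person is a
case iff liability exceeds the normal-theory quantile of the theoretical
liability distribution at 1 - prevalence.  Pleiotropy blocks assign a common
causal SNP set to several diseases; a block may flip the effect sign for some
member (antagonistic pleiotropy), producing disease pairs that share
associated variants yet co-occur *less* than chance -- the realistic failure
mode of the shared-variant comorbidity assumption, and the source of negative
validation labels.

Diagnosis records are an imperfect view of disease status: true cases are
recorded with probability ``diagnosis_sensitivity`` and non-cases with
probability ``1 - diagnosis_specificity``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .io import DiagnosisRecord, GenotypeMatrix, PhenotypeInfo, SummaryStatRecord

log = logging.getLogger(__name__)

DISEASE_CATEGORIES = (
    "pregnancy complications",
    "circulatory system",
    "endocrine/metabolic",
    "genitourinary",
    "digestive",
)


@dataclass(frozen=True)
class PleiotropyBlock:
    """A set of diseases sharing ``n_shared`` causal SNPs.

    ``signs`` gives the per-disease effect sign on the shared SNPs (+1 risk,
    -1 protective); default all +1.
    """

    diseases: tuple[int, ...]
    n_shared: int
    signs: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.diseases) < 2:
            raise ValueError("a pleiotropy block needs at least 2 diseases")
        if len(set(self.diseases)) != len(self.diseases):
            raise ValueError("duplicate disease index in block")
        if self.n_shared < 1:
            raise ValueError("n_shared must be >= 1")
        if self.signs is not None:
            if len(self.signs) != len(self.diseases):
                raise ValueError("signs length must match diseases length")
            if not set(self.signs) <= {-1, 1}:
                raise ValueError("signs must be +1 or -1")

    def sign_of(self, disease: int) -> int:
        if self.signs is None:
            return 1
        return self.signs[self.diseases.index(disease)]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of the synthetic cohort."""

    n_individuals: int = 5000
    n_snps: int = 500
    n_diseases: int = 15
    maf_low: float = 0.05
    maf_high: float = 0.5
    causal_per_disease: int = 20
    pleiotropy_blocks: tuple[PleiotropyBlock, ...] = ()
    effect_size: float = 0.5
    prevalence: float = 0.2
    diagnosis_sensitivity: float = 0.9
    diagnosis_specificity: float = 0.99
    seed: int = 0
    spacing_bp: int = 50_000
    ld_block_size: int = 1
    ld_block_r2: float = 0.0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if not (0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
        if not (0 < self.causal_per_disease <= self.n_snps):
            raise ValueError("causal_per_disease must be in [1, n_snps]")
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must be in (0,1)")
        for prob, name in (
            (self.diagnosis_sensitivity, "diagnosis_sensitivity"),
            (self.diagnosis_specificity, "diagnosis_specificity"),
        ):
            if not (0 <= prob <= 1):
                raise ValueError(f"{name} must be in [0,1]")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if not (0 <= self.ld_block_r2 < 1):
            raise ValueError("ld_block_r2 must be in [0,1)")
        shared_per_disease = np.zeros(self.n_diseases, dtype=int)
        for block in self.pleiotropy_blocks:
            if max(block.diseases) >= self.n_diseases:
                raise ValueError(
                    f"block disease index {max(block.diseases)} out of range "
                    f"(n_diseases={self.n_diseases})"
                )
            for d in block.diseases:
                shared_per_disease[d] += block.n_shared
        if (shared_per_disease > self.causal_per_disease).any():
            raise ValueError(
                "a disease's shared causal SNPs across blocks exceed causal_per_disease"
            )

    @property
    def liability_sd(self) -> float:
        """Theoretical SD of the liability with standardized dosages."""
        return float(np.sqrt(self.causal_per_disease * self.effect_size**2 + 1))

    @property
    def liability_threshold(self) -> float:
        return float(self.liability_sd * stats.norm.ppf(1 - self.prevalence))


def phecode_of(disease_index: int) -> str:
    """Synthetic PheCode for a simulated disease (three digits, no decimals)."""
    return str(100 + disease_index)


def phenotype_table(config: SimulationConfig) -> list[PhenotypeInfo]:
    """Phenotype metadata for the simulated diseases (categories cycle)."""
    return [
        PhenotypeInfo(
            phecode=phecode_of(i),
            name=f"synthetic disease {phecode_of(i)}",
            category=DISEASE_CATEGORIES[i % len(DISEASE_CATEGORIES)],
            sex_specific="none",
        )
        for i in range(config.n_diseases)
    ]


def snp_id_of(snp_index: int) -> str:
    return f"snp{snp_index:04d}"


@dataclass
class SyntheticCohort:
    """Genotypes, true disease statuses, and planted causal structure."""

    genotypes: GenotypeMatrix
    disease_status: np.ndarray  # person x disease, {0,1}
    causal_sets: dict[str, set[str]]  # phecode -> causal SNP ids
    causal_signs: dict[str, dict[str, int]]  # phecode -> snp_id -> sign
    mafs: np.ndarray  # true per-SNP maf
    config: SimulationConfig

    @property
    def phecodes(self) -> list[str]:
        return [phecode_of(i) for i in range(self.config.n_diseases)]

    def phenotype_info(self) -> list[PhenotypeInfo]:
        return phenotype_table(self.config)


def _allocate_causal_sets(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[int, list[int]], dict[int, dict[int, int]]]:
    """Assign causal SNP indices so blocks share exactly n_shared SNPs.

    Shared sets of distinct blocks, and all private fills, are mutually
    disjoint, so the pairwise overlap of two diseases is exactly the sum of
    n_shared over the blocks containing both.
    """
    pool = list(rng.permutation(config.n_snps))
    causal: dict[int, list[int]] = {d: [] for d in range(config.n_diseases)}
    signs: dict[int, dict[int, int]] = {d: {} for d in range(config.n_diseases)}

    def take(k: int) -> list[int]:
        if len(pool) < k:
            raise ValueError(
                "n_snps too small for the requested causal sets and blocks"
            )
        out = pool[:k]
        del pool[:k]
        return out

    for block in config.pleiotropy_blocks:
        shared = take(block.n_shared)
        for d in block.diseases:
            causal[d].extend(shared)
            for s in shared:
                signs[d][s] = block.sign_of(d)
    for d in range(config.n_diseases):
        fill = take(config.causal_per_disease - len(causal[d]))
        causal[d].extend(fill)
        for s in fill:
            signs[d][s] = 1
    return causal, signs


def _draw_genotypes(config: SimulationConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Genotypes (n x m) and per-SNP mafs, optionally with block LD."""
    n, m = config.n_individuals, config.n_snps
    if config.ld_block_size == 1:
        mafs = rng.uniform(config.maf_low, config.maf_high, size=m)
        geno = rng.binomial(2, mafs[None, :], size=(n, m))
        return geno.astype(np.int8), mafs
    # block-LD mode: SNPs within a block share the anchor's maf; follower
    # alleles copy the anchor allele with probability sqrt(target R2)
    mafs = np.empty(m)
    alleles = np.empty((n, 2, m), dtype=np.int8)
    q = np.sqrt(config.ld_block_r2)
    for j in range(m):
        anchor = j - (j % config.ld_block_size)
        if j == anchor:
            mafs[j] = rng.uniform(config.maf_low, config.maf_high)
            alleles[:, :, j] = rng.binomial(1, mafs[j], size=(n, 2))
        else:
            mafs[j] = mafs[anchor]
            fresh = rng.binomial(1, mafs[j], size=(n, 2))
            copy = rng.random(size=(n, 2)) < q
            alleles[:, :, j] = np.where(copy, alleles[:, :, anchor], fresh)
    return alleles.sum(axis=1, dtype=np.int8), mafs


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort; a pure function of the config (incl. seed)."""
    rng = np.random.default_rng(config.seed)
    geno, mafs = _draw_genotypes(config, rng)
    causal_idx, sign_idx = _allocate_causal_sets(config, rng)

    # standardized dosages of causal SNPs only (computed lazily per disease)
    status = np.zeros((config.n_individuals, config.n_diseases), dtype=np.int8)
    threshold = config.liability_threshold
    for d in range(config.n_diseases):
        idx = np.array(causal_idx[d], dtype=int)
        sgn = np.array([sign_idx[d][s] for s in causal_idx[d]], dtype=float)
        m = mafs[idx]
        z = (geno[:, idx] - 2 * m) / np.sqrt(2 * m * (1 - m))
        liability = config.effect_size * (z * sgn).sum(axis=1)
        liability += rng.standard_normal(config.n_individuals)
        status[:, d] = liability > threshold

    person_ids = [f"p{i:05d}" for i in range(config.n_individuals)]
    snp_ids = [snp_id_of(j) for j in range(config.n_snps)]
    causal_sets = {
        phecode_of(d): {snp_id_of(j) for j in causal_idx[d]}
        for d in range(config.n_diseases)
    }
    causal_signs = {
        phecode_of(d): {snp_id_of(j): s for j, s in sign_idx[d].items()}
        for d in range(config.n_diseases)
    }
    return SyntheticCohort(
        genotypes=GenotypeMatrix(person_ids, snp_ids, geno),
        disease_status=status,
        causal_sets=causal_sets,
        causal_signs=causal_signs,
        mafs=mafs,
        config=config,
    )


def allelic_chi2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared (1 df) for a 2x2 allele-count table.

    chi2 = N (ad - bc)^2 / (r1 r2 c1 c2); a zero margin gives chi2 = 0,
    p = 1.  The p-value is floored at 1e-300 so downstream range invariants
    (p > 0) survive extreme statistics.
    """
    a, b = float(table[0, 0]), float(table[0, 1])
    c, d = float(table[1, 0]), float(table[1, 1])
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 0.0, 1.0
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(chi2), max(float(stats.chi2.sf(chi2, df=1)), 1e-300)


def association_scan(cohort: SyntheticCohort) -> list[SummaryStatRecord]:
    """Allelic chi-squared scan of every (disease, SNP) pair.

    For each pair a 2x2 allele-count table (minor/major x case/control) is
    tested on 1 df.  MAF is computed from the full cohort; monomorphic SNPs
    are dropped with a warning, and diseases with zero cases or zero controls
    are skipped with a warning.  Positions lie on one synthetic chromosome
    with SNPs ``spacing_bp`` apart.
    """
    config = cohort.config
    geno = cohort.genotypes.dosages
    n = geno.shape[0]
    alt_counts = geno.sum(axis=0)  # per SNP
    freqs = alt_counts / (2 * n)
    mafs_obs = np.minimum(freqs, 1 - freqs)
    mono = mafs_obs == 0
    if mono.any():
        log.warning("dropping %d monomorphic SNP(s) from the scan", int(mono.sum()))

    records: list[SummaryStatRecord] = []
    for d in range(config.n_diseases):
        cases = cohort.disease_status[:, d].astype(bool)
        n_cases = int(cases.sum())
        if n_cases == 0 or n_cases == n:
            log.warning(
                "disease %s has %d cases out of %d; skipped from the scan",
                phecode_of(d),
                n_cases,
                n,
            )
            continue
        case_alt = geno[cases].sum(axis=0).astype(float)
        ctrl_alt = alt_counts - case_alt
        case_ref = 2.0 * n_cases - case_alt
        ctrl_ref = 2.0 * (n - n_cases) - ctrl_alt
        # vectorized closed form; margins that are zero -> p = 1
        r1 = case_alt + case_ref
        r2 = ctrl_alt + ctrl_ref
        c1 = case_alt + ctrl_alt
        c2 = case_ref + ctrl_ref
        total = r1 + r2
        denom = r1 * r2 * c1 * c2
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = np.where(
                denom > 0,
                total * (case_alt * ctrl_ref - case_ref * ctrl_alt) ** 2 / denom,
                0.0,
            )
        pvals = np.where(denom > 0, stats.chi2.sf(chi2, df=1), 1.0)
        pvals = np.maximum(pvals, 1e-300)
        for j in range(config.n_snps):
            if mono[j]:
                continue
            records.append(
                SummaryStatRecord(
                    phecode=phecode_of(d),
                    snp_id=snp_id_of(j),
                    chrom="1",
                    pos=(j + 1) * config.spacing_bp,
                    pvalue=float(pvals[j]),
                    maf=float(mafs_obs[j]),
                    n_cases=n_cases,
                )
            )
    return records


def emit_diagnoses(cohort: SyntheticCohort, seed: int) -> list[DiagnosisRecord]:
    """Sample PheCode diagnosis records from true disease status.

    True cases are recorded with probability ``diagnosis_sensitivity``; a
    non-case acquires a spurious record with probability
    ``1 - diagnosis_specificity``.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    config = cohort.config
    draws = rng.random(cohort.disease_status.shape)
    is_case = cohort.disease_status.astype(bool)
    prob = np.where(is_case, config.diagnosis_sensitivity, 1 - config.diagnosis_specificity)
    recorded = draws < prob
    person_ids = cohort.genotypes.person_ids
    return [
        DiagnosisRecord(person_id=person_ids[i], code=phecode_of(d), code_system="PheCode")
        for i, d in np.argwhere(recorded)
    ]


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of a config with a different seed."""
    return replace(config, seed=seed)
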