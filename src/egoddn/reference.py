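"""Reference synthetic study: the fixed conditions for the end-to-end run.

Fifteen diseases form three independent ego groups of five.  In group k
(diseases are named by synthetic PheCodes 100..114):

* ego_k           -- the focal obstetric-style disease;
* A_k (+10)       -- shares 10 causal SNPs with the ego (strong comorbidity);
* B_k (+5, +5, +10) -- shares 5 causal SNPs with the ego, 5 with A_k, and 10
  with the decoy D_k (moderate comorbidity, but a hub in the full DDN);
* C_k (-5)        -- shares 5 causal SNPs with the ego with *flipped* effect
  sign (antagonistic pleiotropy): connected in the DDN yet negatively
  correlated in the diagnoses, i.e. a true negative label;
* D_k (0)         -- shares nothing with the ego; its only edge is to B_k.

Ego-alter causal overlaps therefore take values in {0, 5, 10}.  On the
egocentric network the propagation ranks A_k > B_k > C_k (B_k is boosted by
its alter-alter edge to A_k), matching the labels (+, +, -).  On the full DDN
the decoy D_k drains B_k's score below C_k's, degrading the ranking -- the
mechanism by which full-diseasome propagation underperforms the egocentric
one.

Cohort scale: 5,000 individuals, 500 SNPs, effect size 0.5 per standardized
allele, prevalence 0.2, MAF ~ Uniform(0.02, 0.10) (low-frequency risk
variants keep shared-SNP carrier status informative for the individual-level
stratification), diagnosis sensitivity 0.9 / specificity 0.99.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .comorbidity import ComorbidityStat, label_alters
from .evaluate import EvaluationReport, compare_networks
from .network import build_full_ddn, extract_ego_network
from .preprocess import FilterConfig, build_matrix, filter_associations, ld_prune
from .propagate import score_all_egos
from .simulate import (
    PleiotropyBlock,
    SimulationConfig,
    association_scan,
    emit_diagnoses,
    phecode_of,
    simulate_cohort,
)
from .stratify import StratificationResult, stratify_pair

N_GROUPS = 3

# indices within each group-of-five layout
EGO_INDICES = tuple(range(N_GROUPS))


def reference_blocks() -> tuple[PleiotropyBlock, ...]:
    blocks: list[PleiotropyBlock] = []
    for k in range(N_GROUPS):
        ego, a, b, c, d = k, 3 + k, 6 + k, 9 + k, 12 + k
        blocks.append(PleiotropyBlock((ego, a), 10))
        blocks.append(PleiotropyBlock((ego, b), 5))
        blocks.append(PleiotropyBlock((a, b), 5))
        blocks.append(PleiotropyBlock((b, d), 10))
        blocks.append(PleiotropyBlock((ego, c), 5, signs=(1, -1)))
    return tuple(blocks)


def reference_config(seed: int = 0) -> SimulationConfig:
    return SimulationConfig(
        n_individuals=5000,
        n_snps=500,
        n_diseases=15,
        maf_low=0.02,
        maf_high=0.10,
        causal_per_disease=25,
        pleiotropy_blocks=reference_blocks(),
        effect_size=0.5,
        prevalence=0.2,
        diagnosis_sensitivity=0.9,
        diagnosis_specificity=0.99,
        seed=seed,
    )


def reference_egos() -> list[str]:
    return [phecode_of(k) for k in EGO_INDICES]


@dataclass
class ReferenceRun:
    """All evaluation outputs of one seeded end-to-end reference run."""

    seed: int
    reports: list[EvaluationReport]
    summary: dict[str, float]
    truths: dict[str, dict[str, ComorbidityStat]]
    stratifications: dict[str, StratificationResult]  # ego -> result for its +10 alter


def run_reference(seed: int, mu: float = 1.0, weighting: str = "cosine") -> ReferenceRun:
    """Simulate, preprocess, build networks, score, validate, and stratify.

    One complete pipeline pass at the reference conditions for one seed;
    used by the acceptance checks and the worked examples.
    """
    config = reference_config(seed)
    cohort = simulate_cohort(config)
    records = association_scan(cohort)
    phenos = cohort.phenotype_info()

    cfg = FilterConfig()
    kept = filter_associations(records, phenos, cfg)
    kept = ld_prune(kept, cohort.genotypes, cfg)
    matrix = build_matrix(kept)
    ddn = build_full_ddn(matrix, phenos)

    diagnoses = emit_diagnoses(cohort, seed=config.seed + 1)
    cohort_ids = cohort.genotypes.person_ids

    egos = [e for e in reference_egos() if e in ddn.phenotypes and ddn.degree(e) > 0]
    pairs = score_all_egos(ddn, egos, mu=mu, weighting=weighting)
    truths = {
        ego: label_alters(extract_ego_network(ddn, ego), diagnoses, cohort_ids)
        for ego in pairs
    }
    reports, summary = compare_networks(pairs, truths)

    stratifications: dict[str, StratificationResult] = {}
    for k in EGO_INDICES:
        ego, alter = phecode_of(k), phecode_of(3 + k)  # the +10-overlap pair
        if ego in ddn.phenotypes and ddn.has_edge(ego, alter):
            stratifications[ego] = stratify_pair(
                ego, alter, ddn.edge(ego, alter), cohort.genotypes, diagnoses
            )
    return ReferenceRun(seed, reports, summary, truths, stratifications)


def run_reference_seeds(
    seeds: list[int], mu: float = 1.0, weighting: str = "cosine"
) -> list[ReferenceRun]:
    return [run_reference(s, mu=mu, weighting=weighting) for s in seeds]


def summarize_runs(runs: list[ReferenceRun]) -> dict[str, float]:
    """Across-seed summary: mean AUCs/rhos, seed-win fractions, OR recovery."""
    ego_aucs = [r.summary["mean_auc_ego"] for r in runs]
    full_aucs = [r.summary["mean_auc_full"] for r in runs]
    ego_rhos = [r.summary["mean_rho_ego"] for r in runs]
    full_rhos = [r.summary["mean_rho_full"] for r in runs]
    wins = sum(e > f for e, f in zip(ego_aucs, full_aucs))
    rho_pos = sum(r > 0 for r in ego_rhos)
    ors = [s.odds_ratio for r in runs for s in r.stratifications.values()]
    return {
        "mean_auc_ego": float(np.mean(ego_aucs)),
        "mean_auc_full": float(np.mean(full_aucs)),
        "mean_rho_ego": float(np.mean(ego_rhos)),
        "mean_rho_full": float(np.mean(full_rhos)),
        "seeds_ego_auc_higher": float(wins),
        "seeds_rho_positive": float(rho_pos),
        "n_seeds": float(len(runs)),
        "carrier_or_gt1_fraction": float(np.mean([o > 1 for o in ors])) if ors else float("nan"),
        "median_carrier_or": float(np.median(ors)) if ors else float("nan"),
    }
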