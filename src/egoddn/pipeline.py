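"""End-to-end pipeline orchestration with deterministic artifacts.

``run_all`` composes simulate -> preprocess -> build-network -> per-ego
(ego-network, score, ground-truth) -> evaluate -> stratify, writing every
intermediate as a plain-text artifact plus a manifest listing SHA-256 hashes,
the configuration, the seed, and the package version.  Identical config and
seed produce byte-identical artifacts.  The single global seed is expanded
into per-stage sub-seeds by hashing the stage name, so any stage rerun in
isolation reproduces its output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .comorbidity import ComorbidityStat, label_alters
from .evaluate import EvaluationReport, compare_networks
from .io import fmt_float, write_diagnoses, write_genotypes, write_matrix_triplets, write_phenotype_info, write_summary_stats
from .network import build_full_ddn, extract_ego_network, write_network
from .preprocess import FilterConfig, build_matrix, filter_associations, ld_prune
from .propagate import quartile_groups, score_all_egos
from .simulate import (
    PleiotropyBlock,
    SimulationConfig,
    association_scan,
    emit_diagnoses,
    simulate_cohort,
    with_seed,
)
from .stratify import stratify_pair

log = logging.getLogger(__name__)


def stage_seed(seed: int, stage: str) -> int:
    """Derive a reproducible per-stage sub-seed (< 2^31) from the global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Union of simulation and filtering parameters plus scoring options."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    mu: float = 1.0
    weighting: str = "cosine"
    egos: tuple[str, ...] = ()
    stratify_pairs: tuple[tuple[str, str], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.egos:
            raise ValueError("ego list must be non-empty")
        if self.weighting not in ("cosine", "count"):
            raise ValueError(f"weighting must be 'cosine' or 'count': {self.weighting}")
        if self.mu <= 0:
            raise ValueError("mu must be positive")


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from a YAML file mirroring the CLI flags."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    blocks = tuple(
        PleiotropyBlock(
            diseases=tuple(b["diseases"]),
            n_shared=int(b["n_shared"]),
            signs=tuple(b["signs"]) if b.get("signs") else None,
        )
        for b in raw.pop("pleiotropy_blocks", [])
    )
    seed = int(raw.pop("seed", 0))
    sim_keys = set(SimulationConfig.__dataclass_fields__) - {"seed", "pleiotropy_blocks"}
    filt_keys = FilterConfig.__dataclass_fields__.keys()
    sim_kwargs = {k: raw.pop(k) for k in list(raw) if k in sim_keys}
    filt_kwargs = {k: raw.pop(k) for k in list(raw) if k in filt_keys}
    if "exclude_sex" in filt_kwargs:
        filt_kwargs["exclude_sex"] = frozenset(filt_kwargs["exclude_sex"])
    return PipelineConfig(
        sim=SimulationConfig(**sim_kwargs, pleiotropy_blocks=blocks, seed=seed),
        filters=FilterConfig(**filt_kwargs),
        mu=float(raw.pop("mu", 1.0)),
        weighting=str(raw.pop("weighting", "cosine")),
        egos=tuple(str(e) for e in raw.pop("egos", ())),
        stratify_pairs=tuple(
            (str(a), str(b)) for a, b in raw.pop("stratify_pairs", ())
        ),
        seed=seed,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_scores(pairs, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("phecode\traw_score\tnormalized_score\tquartile_group\tnetwork\n")
        for ego in sorted(pairs):
            pair = pairs[ego]
            groups = quartile_groups(pair.ego_result)
            for network_type, result in (("ego", pair.ego_result), ("full", pair.full_result)):
                for alter in pair.alters:
                    fh.write(
                        "\t".join(
                            (
                                alter,
                                fmt_float(result.raw[alter]),
                                fmt_float(result.normalized[alter]),
                                groups[alter] if network_type == "ego" else "-",
                                network_type,
                            )
                        )
                        + "\n"
                    )


def _write_truth(truth: dict[str, ComorbidityStat], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("phecode\tC_ij\tP_i\tP_j\tN\tphi\tpvalue\tis_comorbid\n")
        for alter in sorted(truth):
            s = truth[alter]
            fh.write(
                "\t".join(
                    (
                        alter,
                        str(s.c_ij),
                        str(s.p_i),
                        str(s.p_j),
                        str(s.n),
                        fmt_float(s.phi),
                        fmt_float(s.pvalue),
                        str(s.is_comorbid),
                    )
                )
                + "\n"
            )


def _write_report(reports: list[EvaluationReport], summary: dict[str, float], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("ego\tnetwork\tauc\tspearman_rho\tspearman_pvalue\tn_alters\tn_positive\n")
        for r in reports:
            fh.write(
                "\t".join(
                    (
                        r.ego,
                        r.network_type,
                        fmt_float(r.auc) if r.auc is not None else "undefined",
                        fmt_float(r.spearman_rho),
                        fmt_float(r.spearman_pvalue),
                        str(r.n_alters),
                        str(r.n_positive),
                    )
                )
                + "\n"
            )
        fh.write(
            "summary\tboth\t"
            + "\t".join(
                fmt_float(summary[k])
                for k in ("mean_auc_ego", "mean_auc_full", "mean_rho_ego", "mean_rho_full")
            )
            + "\t-\t-\n"
        )


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict[str, str]:
    """Run the full pipeline; returns {artifact name: sha256}.

    Every stage's output is written under ``out_dir``; a ``manifest.json``
    records hashes, config, seed, and package version.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def stage(name: str):
        log.info("stage: %s", name)

    stage("simulate")
    sim_config = with_seed(config.sim, stage_seed(config.seed, "simulate"))
    cohort = simulate_cohort(sim_config)
    records = association_scan(cohort)
    phenos = cohort.phenotype_info()
    diagnoses = emit_diagnoses(cohort, seed=stage_seed(config.seed, "diagnoses"))

    write_genotypes(cohort.genotypes, out / "genotypes.tsv")
    write_summary_stats(records, out / "summary_stats.tsv")
    write_diagnoses(diagnoses, out / "diagnoses.tsv")
    write_phenotype_info(phenos, out / "phenotype_info.csv")
    write_matrix_triplets(
        [(p, s) for p, snps in sorted(cohort.causal_sets.items()) for s in sorted(snps)],
        out / "truth_causal_sets.tsv",
    )
    artifacts += [
        out / "genotypes.tsv",
        out / "summary_stats.tsv",
        out / "diagnoses.tsv",
        out / "phenotype_info.csv",
        out / "truth_causal_sets.tsv",
    ]

    stage("preprocess")
    kept = filter_associations(records, phenos, config.filters)
    kept = ld_prune(kept, cohort.genotypes, config.filters)
    matrix = build_matrix(kept)
    write_matrix_triplets(matrix.to_pairs(), out / "matrix.tsv")
    artifacts.append(out / "matrix.tsv")

    stage("build-network")
    ddn = build_full_ddn(matrix, phenos)
    write_network(ddn, out / "ddn.graphml", format="graphml")
    write_network(ddn, out / "ddn_edges.tsv", format="edge_tsv")
    artifacts += [out / "ddn.graphml", out / "ddn_edges.tsv"]

    stage("score")
    egos = [e for e in config.egos if e in ddn.phenotypes and ddn.degree(e) > 0]
    missing = set(config.egos) - set(egos)
    if missing:
        log.warning("ego(s) absent or isolated in the DDN, skipped: %s", sorted(missing))
    pairs = score_all_egos(ddn, egos, mu=config.mu, weighting=config.weighting)
    for ego in sorted(pairs):
        net = extract_ego_network(ddn, ego)
        write_network(net, out / f"ego_{ego}.graphml", format="graphml")
        artifacts.append(out / f"ego_{ego}.graphml")
    _write_scores(pairs, out / "scores.tsv")
    artifacts.append(out / "scores.tsv")

    stage("ground-truth")
    cohort_ids = cohort.genotypes.person_ids
    truths = {
        ego: label_alters(extract_ego_network(ddn, ego), diagnoses, cohort_ids)
        for ego in pairs
    }
    for ego in sorted(truths):
        path = out / f"truth_{ego}.tsv"
        _write_truth(truths[ego], path)
        artifacts.append(path)

    stage("evaluate")
    reports, summary = compare_networks(pairs, truths)
    _write_report(reports, summary, out / "report.tsv")
    artifacts.append(out / "report.tsv")

    stage("stratify")
    strat_pairs = list(config.stratify_pairs)
    if not strat_pairs and pairs:
        # default: first ego with its most-sharing alter
        ego = sorted(pairs)[0]
        alter = max(
            pairs[ego].alters, key=lambda a: (ddn.edge(ego, a).count_weight, a)
        )
        strat_pairs = [(ego, alter)]
    with open(out / "stratification.tsv", "w") as fh:
        fh.write(
            "ego\talter\tcarrier_both\tcarrier_ego_only\tnoncarrier_both\t"
            "noncarrier_ego_only\tchi2\tpvalue\todds_ratio\n"
        )
        for ego, alter in strat_pairs:
            if not ddn.has_edge(ego, alter):
                log.warning("no DDN edge between %s and %s; skipped", ego, alter)
                continue
            res = stratify_pair(ego, alter, ddn.edge(ego, alter), cohort.genotypes, diagnoses)
            t = res.table
            fh.write(
                "\t".join(
                    (
                        ego,
                        alter,
                        str(t.carrier_both),
                        str(t.carrier_ego_only),
                        str(t.noncarrier_both),
                        str(t.noncarrier_ego_only),
                        fmt_float(res.chi2),
                        fmt_float(res.pvalue),
                        fmt_float(res.odds_ratio),
                    )
                )
                + "\n"
            )
    artifacts.append(out / "stratification.tsv")

    hashes = {p.name: _sha256(p) for p in artifacts}
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            "sim": _jsonable(asdict(config.sim)),
            "filters": _jsonable(asdict(config.filters)),
            "mu": config.mu,
            "weighting": config.weighting,
            "egos": list(config.egos),
            "stratify_pairs": [list(p) for p in config.stratify_pairs],
        },
        "artifacts": hashes,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return hashes


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, frozenset):
        return sorted(obj)
    return obj
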