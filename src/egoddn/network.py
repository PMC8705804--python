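"""Disease-disease network (DDN) construction and egocentric extraction.

Nodes are PheCode phenotypes; two diseases are connected iff they share at
least one significantly associated SNP.  Each edge carries both weighting
schemes: the cosine similarity of the binary association vectors
(w_ij = |S_i ∩ S_j| / sqrt(|S_i|·|S_j|)) and the raw shared-SNP count, plus
the sorted list of shared SNP ids.  An egocentric network is the induced
subgraph on a focal (ego) disease and its direct neighbours (alter diseases);
alter-alter edges are kept so that label propagation sees the local topology,
not just the star.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .io import PhenotypeInfo, SchemaError, fmt_float
from .preprocess import DiseaseSnpMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EdgeAnnotation:
    """Shared-SNP annotation for one disease pair."""

    shared_snp_ids: tuple[str, ...]  # sorted
    cosine_weight: float
    count_weight: int

    @property
    def n_shared_snps(self) -> int:
        return self.count_weight

    def weight(self, weighting: str) -> float:
        if weighting == "cosine":
            return self.cosine_weight
        if weighting == "count":
            return float(self.count_weight)
        raise ValueError(f"unknown weighting {weighting!r}; use 'cosine' or 'count'")


def _edge_key(a: str, b: str) -> tuple[str, str]:
    if a == b:
        raise ValueError(f"self-loop on node {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass
class WeightedDdn:
    """Undirected weighted disease-disease network.

    ``phenotypes`` maps each node's phecode to its metadata; ``edges`` maps
    lexicographically ordered phecode pairs to their annotation.  Isolated
    nodes (no shared SNPs with anyone) are retained.
    """

    phenotypes: dict[str, PhenotypeInfo]
    edges: dict[tuple[str, str], EdgeAnnotation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._adj: dict[str, set[str]] = {p: set() for p in self.phenotypes}
        for (a, b), ann in self.edges.items():
            if (a, b) != _edge_key(a, b):
                raise ValueError(f"edge key {(a, b)} not in canonical order")
            if a not in self.phenotypes or b not in self.phenotypes:
                raise ValueError(f"edge {(a, b)} references unknown node")
            if ann.count_weight < 1:
                raise ValueError(f"edge {(a, b)} has no shared SNPs")
            self._adj[a].add(b)
            self._adj[b].add(a)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.phenotypes)

    def neighbors(self, phecode: str) -> list[str]:
        return sorted(self._adj[phecode])

    def degree(self, phecode: str) -> int:
        return len(self._adj[phecode])

    def edge(self, a: str, b: str) -> EdgeAnnotation:
        return self.edges[_edge_key(a, b)]

    def has_edge(self, a: str, b: str) -> bool:
        return _edge_key(a, b) in self.edges

    def subgraph(self, nodes: list[str]) -> "WeightedDdn":
        keep = set(nodes)
        unknown = keep - set(self.phenotypes)
        if unknown:
            raise KeyError(f"nodes not in DDN: {sorted(unknown)}")
        return WeightedDdn(
            phenotypes={p: self.phenotypes[p] for p in sorted(keep)},
            edges={k: v for k, v in self.edges.items() if k[0] in keep and k[1] in keep},
        )

    def weight_matrix(self, weighting: str = "cosine") -> tuple[list[str], np.ndarray]:
        """Dense symmetric adjacency matrix in sorted-node order."""
        order = self.nodes
        idx = {p: i for i, p in enumerate(order)}
        w = np.zeros((len(order), len(order)))
        for (a, b), ann in self.edges.items():
            w[idx[a], idx[b]] = w[idx[b], idx[a]] = ann.weight(weighting)
        return order, w

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for p in self.nodes:
            info = self.phenotypes[p]
            g.add_node(
                p,
                phecode=p,
                name=info.name,
                category=info.category,
                sex_specific=info.sex_specific,
                degree=self.degree(p),
            )
        for (a, b), ann in self.edges.items():
            g.add_edge(
                a,
                b,
                weight=ann.cosine_weight,
                n_shared_snps=ann.count_weight,
                shared_snp_ids=";".join(ann.shared_snp_ids),
            )
        return g


@dataclass
class EgoNetwork:
    """Induced subgraph on one ego disease and its direct neighbours."""

    ego: str
    alters: list[str]  # sorted phecodes
    graph: WeightedDdn

    @property
    def nodes(self) -> list[str]:
        return self.graph.nodes


def build_full_ddn(
    matrix: DiseaseSnpMatrix, phenos: list[PhenotypeInfo] | None = None
) -> WeightedDdn:
    """Construct the complete DDN from a binary disease-SNP matrix.

    Every pair of diseases sharing at least one associated SNP is connected;
    the cosine weight is the cosine similarity of the two binary association
    vectors and the count weight is the size of the shared-SNP set.
    """
    info = {p.phecode: p for p in (phenos or [])}
    phenotypes: dict[str, PhenotypeInfo] = {}
    for code in matrix.phecodes:
        phenotypes[code] = info.get(
            code, PhenotypeInfo(code, name=code, category="unknown", sex_specific="none")
        )

    a = matrix.assoc.astype(np.int64)
    shared = a @ a.T  # pairwise shared-SNP counts
    sizes = a.sum(axis=1)
    snp_arr = np.asarray(matrix.snp_ids, dtype=object)
    edges: dict[tuple[str, str], EdgeAnnotation] = {}
    n = len(matrix.phecodes)
    for i in range(n):
        for j in range(i + 1, n):
            c = int(shared[i, j])
            if c == 0:
                continue
            ids = tuple(sorted(snp_arr[(a[i] == 1) & (a[j] == 1)]))
            cos = c / np.sqrt(float(sizes[i]) * float(sizes[j]))
            key = _edge_key(matrix.phecodes[i], matrix.phecodes[j])
            edges[key] = EdgeAnnotation(ids, float(cos), c)
    return WeightedDdn(phenotypes, edges)


def extract_ego_network(ddn: WeightedDdn, ego: str, star_only: bool = False) -> EgoNetwork:
    """Extract the egocentric network for ``ego``.

    Alters are all diseases sharing at least one SNP with the ego; the induced
    subgraph keeps alter-alter edges unless ``star_only`` is set.
    """
    if ego not in ddn.phenotypes:
        raise KeyError(f"ego disease {ego!r} not in DDN")
    alters = ddn.neighbors(ego)
    if not alters:
        raise ValueError(f"isolated ego-disease {ego!r}: no egocentric network")
    sub = ddn.subgraph([ego, *alters])
    if star_only:
        sub = WeightedDdn(
            phenotypes=sub.phenotypes,
            edges={k: v for k, v in sub.edges.items() if ego in k},
        )
    return EgoNetwork(ego=ego, alters=alters, graph=sub)


def category_composition(net: EgoNetwork, phenos: list[PhenotypeInfo]) -> dict[str, int]:
    """Count alter diseases (ego excluded) per disease category."""
    info = {p.phecode: p for p in phenos}
    counts: dict[str, int] = {}
    for alter in net.alters:
        if alter not in info:
            raise KeyError(f"no phenotype metadata for alter {alter!r}")
        info[alter].validate()
        counts[info[alter].category] = counts.get(info[alter].category, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# serialization

NETWORK_FORMATS = ("graphml", "edge_tsv")

EDGE_TSV_COLUMNS = ("phecode_a", "phecode_b", "weight", "n_shared_snps", "shared_snp_ids")


def write_network(ddn: WeightedDdn | EgoNetwork, path: str | Path, format: str = "graphml") -> None:
    """Write a DDN (or the graph of an ego network) to GraphML or an edge TSV.

    The edge TSV lists edges sorted by (phecode_a, phecode_b); isolated nodes
    appear only in GraphML output.
    """
    graph = ddn.graph if isinstance(ddn, EgoNetwork) else ddn
    if not graph.phenotypes:
        raise ValueError("cannot write an empty network")
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(graph.to_networkx(), path, named_key_ids=True)
    elif format == "edge_tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(EDGE_TSV_COLUMNS) + "\n")
            for a, b in sorted(graph.edges):
                ann = graph.edges[(a, b)]
                fh.write(
                    "\t".join(
                        (
                            a,
                            b,
                            fmt_float(ann.cosine_weight),
                            str(ann.count_weight),
                            ";".join(ann.shared_snp_ids),
                        )
                    )
                    + "\n"
                )
    else:
        raise ValueError(
            f"unknown network format {format!r}; supported: {', '.join(NETWORK_FORMATS)}"
        )


def read_network(path: str | Path) -> WeightedDdn:
    """Read a GraphML network written by :func:`write_network`."""
    g = nx.read_graphml(Path(path))
    phenotypes: dict[str, PhenotypeInfo] = {}
    for node, attrs in g.nodes(data=True):
        phenotypes[str(node)] = PhenotypeInfo(
            phecode=str(attrs.get("phecode", node)),
            name=str(attrs.get("name", node)),
            category=str(attrs.get("category", "unknown")),
            sex_specific=str(attrs.get("sex_specific", "none")),
        )
    edges: dict[tuple[str, str], EdgeAnnotation] = {}
    for a, b, attrs in g.edges(data=True):
        shared = tuple(s for s in str(attrs.get("shared_snp_ids", "")).split(";") if s)
        count = int(attrs.get("n_shared_snps", len(shared)))
        edges[_edge_key(str(a), str(b))] = EdgeAnnotation(
            shared, float(attrs["weight"]), count
        )
    return WeightedDdn(phenotypes, edges)
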