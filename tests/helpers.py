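"""Independent oracles and graph builders shared across tests.

Everything here deliberately avoids the library's own solution paths:
the propagation oracles use a dense explicit inverse and a Jacobi fixed
point, AUC is counted pair by pair, and chi-squared goes through scipy's
contingency routine.
"""

from __future__ import annotations

import numpy as np

from egoddn.io import PhenotypeInfo
from egoddn.network import EdgeAnnotation, WeightedDdn


def make_graph(weights: dict[tuple[str, str], float], extra_nodes: tuple[str, ...] = ()) -> WeightedDdn:
    """Build a WeightedDdn from an explicit edge-weight dict.

    Cosine and count weights are both set from the given weight (count is a
    placeholder >= 1); shared SNP ids are synthetic.
    """
    nodes = {n for pair in weights for n in pair} | set(extra_nodes)
    phenos = {
        n: PhenotypeInfo(n, name=n, category="test", sex_specific="none") for n in nodes
    }
    edges = {}
    for (a, b), w in weights.items():
        key = (a, b) if a < b else (b, a)
        edges[key] = EdgeAnnotation(
            shared_snp_ids=(f"syn_{key[0]}_{key[1]}",), cosine_weight=float(w), count_weight=1
        )
    return WeightedDdn(phenos, edges)


def random_connected_graph(rng: np.random.Generator, n: int) -> WeightedDdn:
    """Random connected weighted graph: a random spanning tree plus extras."""
    names = [f"n{i:02d}" for i in range(n)]
    weights: dict[tuple[str, str], float] = {}
    order = rng.permutation(n)
    for i in range(1, n):
        a, b = names[order[i]], names[order[int(rng.integers(0, i))]]
        a, b = min(a, b), max(a, b)
        weights[(a, b)] = float(rng.uniform(0.1, 2.0))
    n_extra = int(rng.integers(0, max(1, n)))
    for _ in range(n_extra):
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        a, b = min(names[i], names[j]), max(names[i], names[j])
        weights.setdefault((a, b), float(rng.uniform(0.1, 2.0)))
    return make_graph(weights)


def gssl_dense_inverse(graph: WeightedDdn, ego: str, mu: float, weighting: str = "cosine") -> dict[str, float]:
    """Oracle: f = (I + mu L)^-1 y via an explicit dense matrix inverse."""
    nodes, w = graph.weight_matrix(weighting)
    d = np.diag(w.sum(axis=1))
    laplacian = d - w
    y = np.zeros(len(nodes))
    y[nodes.index(ego)] = 1.0
    f = np.linalg.inv(np.eye(len(nodes)) + mu * laplacian) @ y
    return dict(zip(nodes, f))


def gssl_jacobi(
    graph: WeightedDdn, ego: str, mu: float, weighting: str = "cosine",
    tol: float = 1e-13, max_iter: int = 2_000_000,
) -> dict[str, float]:
    """Oracle: Jacobi fixed point f <- (y + mu W f) / (1 + mu d)."""
    nodes, w = graph.weight_matrix(weighting)
    d = w.sum(axis=1)
    y = np.zeros(len(nodes))
    y[nodes.index(ego)] = 1.0
    f = np.zeros_like(y)
    denom = 1.0 + mu * d
    for _ in range(max_iter):
        f_new = (y + mu * (w @ f)) / denom
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            break
        f = f_new
    return dict(zip(nodes, f))


def auc_brute_force(scores: dict[str, float], labels: dict[str, bool]) -> float:
    """Oracle: pairwise concordance count over positive-negative pairs."""
    pos = [scores[k] for k in scores if labels[k]]
    neg = [scores[k] for k in scores if not labels[k]]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
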