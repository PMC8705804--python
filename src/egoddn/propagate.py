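"""Closed-form graph-based semi-supervised label propagation (GSSL).

Given a weighted undirected graph and a single labelled node (the ego disease,
y_ego = 1, all other entries 0), the score vector f minimizes

    (f - y)' (f - y) + mu * f' L f,

where L = D - W is the graph Laplacian and D the diagonal matrix of weighted
degrees.  The minimizer is the solution of the symmetric positive-definite
system (I + mu L) f = y, solved by sparse factorization (never an explicit
inverse).  Scores are min-max normalized over all nodes of the solved graph;
alter diseases are then stratified into recommendation quartiles of the
normalized score.

On a connected graph the solution conserves mass (sum f = sum y = 1), is
strictly positive, tends to y as mu -> 0 and to the uniform vector as
mu -> infinity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .network import EgoNetwork, WeightedDdn

log = logging.getLogger(__name__)

QUARTILE_GROUPS = ("very_high", "high", "intermediate", "low")


@dataclass
class GsslResult:
    """Propagation scores for one solve.

    ``raw`` holds the solution f of (I + mu L) f = y; ``normalized`` the
    min-max transform f' = (f - min f) / (max f - min f) over all nodes
    (all zeros, with a warning, if f is constant); ``degrees`` the weighted
    Laplacian diagonal d_i = sum_j w_ij.
    """

    ego: str
    nodes: list[str]
    raw: dict[str, float]
    normalized: dict[str, float]
    degrees: dict[str, float]
    mu: float
    weighting: str

    @property
    def alters(self) -> list[str]:
        return [n for n in self.nodes if n != self.ego]


def solve_gssl(
    graph: WeightedDdn | EgoNetwork,
    ego: str | None = None,
    mu: float = 1.0,
    weighting: str = "cosine",
) -> GsslResult:
    """Solve the closed-form propagation problem for a single labelled node.

    For an :class:`EgoNetwork` the ego is implied (and the graph is connected
    by construction).  A disconnected full DDN is handled per component:
    components not containing the labelled node receive score 0.
    """
    if isinstance(graph, EgoNetwork):
        if ego is not None and ego != graph.ego:
            raise ValueError(f"ego {ego!r} does not match network ego {graph.ego!r}")
        ego = graph.ego
        graph = graph.graph
    if ego is None:
        raise ValueError("an ego (labelled node) is required")
    if ego not in graph.phenotypes:
        raise KeyError(f"labelled node {ego!r} not in graph")
    if mu <= 0:
        raise ValueError(f"mu must be positive: {mu}")

    nodes, w = graph.weight_matrix(weighting)
    n = len(nodes)
    y = np.zeros(n)
    y[nodes.index(ego)] = 1.0

    w_sp = sp.csr_matrix(w)
    deg = np.asarray(w_sp.sum(axis=1)).ravel()
    laplacian = sp.diags(deg) - w_sp
    system = (sp.eye(n, format="csc") + mu * laplacian.tocsc())

    n_comp, labels = sp.csgraph.connected_components(w_sp, directed=False)
    if n_comp > 1:
        log.info("graph has %d connected components; unlabeled components score 0", n_comp)
    f = spla.spsolve(system, y)
    f = np.asarray(f).ravel()
    # components without the labelled node solve to exactly 0; snap away
    # factorization dust so downstream comparisons are clean
    f[labels != labels[nodes.index(ego)]] = 0.0

    span = f.max() - f.min()
    if span == 0 or not math.isfinite(span):
        log.warning("constant score vector; normalized scores set to 0")
        f_norm = np.zeros(n)
    else:
        f_norm = (f - f.min()) / span
    return GsslResult(
        ego=ego,
        nodes=nodes,
        raw=dict(zip(nodes, f.tolist())),
        normalized=dict(zip(nodes, f_norm.tolist())),
        degrees=dict(zip(nodes, deg.tolist())),
        mu=mu,
        weighting=weighting,
    )


def quartile_groups(result: GsslResult) -> dict[str, str]:
    """Stratify alters into recommendation quartiles of normalized score.

    Alters are ranked by normalized score descending (ties broken by phecode
    ascending); the first ceil(n/4) fall in ``very_high``, the next ceil(n/4)
    in ``high``, the next in ``intermediate``, and the remainder in ``low``.
    """
    alters = result.alters
    if not alters:
        raise ValueError("no alters to stratify")
    scores = [result.normalized[a] for a in alters]
    if len(set(scores)) == 1:
        log.warning("all alter scores equal; quartile grouping falls back to phecode order")
    ranked = sorted(alters, key=lambda a: (-result.normalized[a], a))
    chunk = math.ceil(len(ranked) / 4)
    groups: dict[str, str] = {}
    for i, alter in enumerate(ranked):
        groups[alter] = QUARTILE_GROUPS[min(i // chunk, 3)]
    return groups


@dataclass
class EgoScorePair:
    """Egocentric and full-DDN scores for one ego, on the same alter set."""

    ego: str
    alters: list[str]
    ego_result: GsslResult
    full_result: GsslResult

    def scores(self, network_type: str) -> dict[str, float]:
        """Raw scores restricted to the alter set."""
        res = self.ego_result if network_type == "ego" else self.full_result
        return {a: res.raw[a] for a in self.alters}


def score_all_egos(
    ddn: WeightedDdn,
    egos: list[str],
    mu: float = 1.0,
    weighting: str = "cosine",
) -> dict[str, EgoScorePair]:
    """Score each ego on its egocentric network and on the full DDN.

    Both solves label only the ego; the full-DDN result is paired with the
    ego's alter set for downstream comparison.  Isolated egos are skipped
    with a warning.
    """
    from .network import extract_ego_network

    out: dict[str, EgoScorePair] = {}
    for ego in egos:
        try:
            net = extract_ego_network(ddn, ego)
        except (KeyError, ValueError) as exc:
            log.warning("skipping ego %s: %s", ego, exc)
            continue
        ego_res = solve_gssl(net, mu=mu, weighting=weighting)
        full_res = solve_gssl(ddn, ego=ego, mu=mu, weighting=weighting)
        out[ego] = EgoScorePair(ego, net.alters, ego_res, full_res)
    return out
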