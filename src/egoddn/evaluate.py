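"""Evaluation of propagation scores against comorbidity ground truth.

AUC uses the rank (Mann-Whitney) method with mid-ranks for ties; Spearman's
rank correlation compares scores with the continuous phi values (two-sided p
from the t approximation, optionally an exact permutation p for small n).
The egocentric and full-DDN conditions are always compared on the same alter
set so the two AUCs score identical instances.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.stats import rankdata

from .comorbidity import ComorbidityStat
from .propagate import EgoScorePair

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvaluationReport:
    """AUC and Spearman rho for one (ego, network type) condition."""

    ego: str
    network_type: str  # "ego" or "full"
    auc: float | None  # None when labels are one-class
    spearman_rho: float
    spearman_pvalue: float
    n_alters: int
    n_positive: int

    @property
    def auc_defined(self) -> bool:
        return self.auc is not None


def compute_auc(scores: dict[str, float], labels: dict[str, bool]) -> float | None:
    """Mann-Whitney AUC of scores against binary labels (mid-rank ties).

    Returns None (undefined) when all labels are positive or all negative.
    """
    keys = sorted(scores)
    if set(keys) != set(labels):
        raise KeyError("scores and labels must cover the same instances")
    y = np.array([bool(labels[k]) for k in keys])
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    s = np.array([scores[k] for k in keys], dtype=float)
    ranks = rankdata(s)  # mid-ranks for ties
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _spearman_exact_pvalue(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided permutation p-value over all orderings (n <= 10)."""
    rx = rankdata(x)
    ry = rankdata(y)
    n = len(rx)
    observed = abs(rho)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        if abs(r) >= observed - 1e-12:
            count += 1
        total += 1
    return count / total


def compute_spearman(
    scores: dict[str, float], phi_values: dict[str, float], exact: bool = False
) -> tuple[float, float]:
    """Spearman rank correlation between scores and phi values.

    Mid-ranks handle ties; the p-value is two-sided via the t approximation
    t = rho * sqrt((n-2)/(1-rho^2)), or an exact permutation test when
    ``exact`` is set (n <= 10 only).
    """
    keys = sorted(scores)
    if set(keys) != set(phi_values):
        raise KeyError("scores and phi values must cover the same instances")
    if len(keys) < 3:
        raise ValueError("Spearman correlation requires at least 3 alters")
    x = np.array([scores[k] for k in keys], dtype=float)
    y = np.array([phi_values[k] for k in keys], dtype=float)
    rx, ry = rankdata(x), rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        return 0.0, 1.0
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if exact:
        if len(keys) > 10:
            raise ValueError("exact permutation p-value limited to n <= 10")
        return rho, _spearman_exact_pvalue(x, y, rho)
    n = len(keys)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    return rho, float(2 * stats.t.sf(abs(t), df=n - 2))


def evaluate_pair(
    pair: EgoScorePair, truth: dict[str, ComorbidityStat]
) -> tuple[EvaluationReport, EvaluationReport]:
    """Reports for the egocentric and full-DDN conditions of one ego."""
    labels = {a: truth[a].is_comorbid for a in pair.alters}
    phis = {a: truth[a].phi for a in pair.alters}
    reports = []
    for network_type in ("ego", "full"):
        scores = pair.scores(network_type)
        auc = compute_auc(scores, labels)
        if len(pair.alters) >= 3:
            rho, pval = compute_spearman(scores, phis)
        else:
            log.warning("ego %s has %d alter(s); Spearman undefined", pair.ego, len(pair.alters))
            rho, pval = math.nan, math.nan
        reports.append(
            EvaluationReport(
                ego=pair.ego,
                network_type=network_type,
                auc=auc,
                spearman_rho=rho,
                spearman_pvalue=pval,
                n_alters=len(pair.alters),
                n_positive=sum(labels.values()),
            )
        )
    return reports[0], reports[1]


def compare_networks(
    pairs: dict[str, EgoScorePair], truths: dict[str, dict[str, ComorbidityStat]]
) -> tuple[list[EvaluationReport], dict[str, float]]:
    """Evaluate every ego under both conditions and summarize.

    The summary holds arithmetic means of AUC and rho per network type over
    egos whose AUC is defined (one-class egos are excluded and logged).
    """
    reports: list[EvaluationReport] = []
    for ego in sorted(pairs):
        ego_rep, full_rep = evaluate_pair(pairs[ego], truths[ego])
        reports.extend((ego_rep, full_rep))

    summary: dict[str, float] = {}
    for network_type in ("ego", "full"):
        defined = [
            r for r in reports if r.network_type == network_type and r.auc_defined
        ]
        skipped = [
            r.ego for r in reports if r.network_type == network_type and not r.auc_defined
        ]
        if skipped:
            log.warning(
                "AUC undefined (one-class labels) for ego(s) %s; excluded from averages",
                ", ".join(skipped),
            )
        summary[f"n_egos_{network_type}"] = float(len(defined))
        if defined:
            summary[f"mean_auc_{network_type}"] = float(
                np.mean([r.auc for r in defined])
            )
            rhos = [r.spearman_rho for r in defined if math.isfinite(r.spearman_rho)]
            summary[f"mean_rho_{network_type}"] = float(np.mean(rhos)) if rhos else math.nan
        else:
            summary[f"mean_auc_{network_type}"] = math.nan
            summary[f"mean_rho_{network_type}"] = math.nan
    return reports, summary
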