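"""Weighted graph-theoretical metrics for SC, FC and USFC connectomes.

Connectivity weights measure strength, so shortest-path metrics use the
standard reciprocal convention: edge length = 1 / weight, no edge when the
weight is zero.  FC matrices must be passed through absolute value first
(negative correlations carry no meaningful path length).

Provided metrics:

* global / nodal efficiency — mean inverse weighted shortest-path length
  over ordered pairs (0 for unreachable pairs);
* local efficiency — global efficiency of each node's neighbor subgraph;
* betweenness centrality — weighted shortest-path betweenness, normalized
  by (N-1)(N-2)/2, shortest-path multiplicity shared fractionally;
* modularity — deterministic greedy agglomerative community detection with
  Q = sum_c [W_c / W - (S_c / 2W)^2], plus a per-node decomposition
  contribution(i) = sum_{j in C(i)} (w_ij - s_i s_j / 2W) / (2W) whose total
  is exactly Q.

``compare_metrics`` computes everything per subject for SC, |FC| and USFC
(each optionally normalized to remove scale differences) and runs paired
t-tests between connectivity types, BH-corrected across nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy import stats as sps
from scipy.sparse.csgraph import dijkstra
from statsmodels.stats.multitest import multipletests

from .io import ValidationError
from .routing import SubjectConnectome
from .traffic import USFCMatrix

CONNECTIVITY_TYPES = ("SC", "FC", "USFC")
GLOBAL_METRICS = ("global_efficiency", "mean_betweenness", "modularity_Q")
NODAL_METRICS = (
    "nodal_efficiency",
    "local_efficiency",
    "betweenness",
    "nodal_modularity_contribution",
)


def _check_weights(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError("expected a square matrix")
    if np.any(m < 0):
        raise ValidationError(
            "negative weights: take absolute values (e.g. |FC|) before graph metrics"
        )
    if np.max(np.abs(m - m.T), initial=0.0) > 1e-9:
        raise ValidationError("expected a symmetric matrix")
    return m


def to_length_graph(matrix: np.ndarray) -> nx.Graph:
    """NetworkX graph with 'weight' (strength) and 'length' (= 1/weight) attributes."""
    m = _check_weights(matrix)
    g = nx.Graph()
    g.add_nodes_from(range(m.shape[0]))
    ii, jj = np.nonzero(np.triu(m, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        w = float(m[i, j])
        g.add_edge(i, j, weight=w, length=1.0 / w)
    return g


def _shortest_lengths(matrix: np.ndarray) -> np.ndarray:
    """All-pairs weighted shortest-path lengths on the reciprocal-length graph."""
    m = _check_weights(matrix)
    with np.errstate(divide="ignore"):
        lengths = np.where(m > 0, 1.0 / np.where(m > 0, m, 1.0), 0.0)
    return dijkstra(lengths, directed=False)


def _efficiency_from_d(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    return float(inv[off].mean())


def global_efficiency(matrix: np.ndarray) -> float:
    """Mean of 1/d(i, j) over ordered pairs; unreachable pairs contribute 0."""
    m = _check_weights(matrix)
    if m.shape[0] < 2:
        raise ValidationError("efficiency needs at least 2 nodes")
    return _efficiency_from_d(_shortest_lengths(m))


def nodal_efficiency(matrix: np.ndarray) -> np.ndarray:
    """Per node: mean of 1/d(i, j) over the other nodes."""
    m = _check_weights(matrix)
    if m.shape[0] < 2:
        raise ValidationError("efficiency needs at least 2 nodes")
    d = _shortest_lengths(m)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    return inv.sum(axis=1, where=off) / (n - 1)


def local_efficiency(matrix: np.ndarray) -> np.ndarray:
    """Per node: global efficiency of the subgraph induced by its neighbors."""
    m = _check_weights(matrix)
    n = m.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(m[i] > 0)
        if nbrs.size < 2:
            continue
        out[i] = _efficiency_from_d(_shortest_lengths(m[np.ix_(nbrs, nbrs)]))
    return out


def betweenness(matrix: np.ndarray, normalized: bool = True) -> tuple[np.ndarray, float]:
    """Weighted shortest-path betweenness per node, plus its mean."""
    g = to_length_graph(matrix)
    bc = nx.betweenness_centrality(g, weight="length", normalized=normalized)
    vec = np.array([bc[i] for i in range(matrix.shape[0])])
    return vec, float(vec.mean())


def modularity_partition(
    matrix: np.ndarray,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Greedy-agglomerative community partition with Q and nodal contributions.

    Returns (community id per node, Q, per-node contribution to Q).  The
    greedy merge is deterministic; community ids are ordered by smallest
    member node.  Isolated nodes form singleton communities (zero
    contribution).
    """
    m = _check_weights(matrix)
    n = m.shape[0]
    if not np.any(np.triu(m, k=1) > 0):
        raise ValidationError("modularity undefined for an edgeless graph")
    g = to_length_graph(matrix)
    communities = nx.algorithms.community.greedy_modularity_communities(g, weight="weight")
    communities = sorted((sorted(c) for c in communities), key=lambda c: c[0])
    partition = np.empty(n, dtype=int)
    for cid, members in enumerate(communities):
        partition[members] = cid

    strength = m.sum(axis=1)
    two_w = strength.sum()  # 2W
    same = partition[:, None] == partition[None, :]
    null = np.outer(strength, strength) / two_w
    contrib = np.where(same, m - null, 0.0).sum(axis=1) / two_w
    q = float(contrib.sum())
    return partition, q, contrib


def modularity_q(matrix: np.ndarray, partition: np.ndarray) -> float:
    """Q of a given partition (same null model as modularity_partition)."""
    m = _check_weights(matrix)
    strength = m.sum(axis=1)
    two_w = strength.sum()
    same = np.asarray(partition)[:, None] == np.asarray(partition)[None, :]
    return float((np.where(same, m - np.outer(strength, strength) / two_w, 0.0)).sum() / two_w)


# ---------------------------------------------------------------------------
# Cohort comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricsComparison:
    """Per-subject metric values per connectivity type, with paired tests."""

    types: tuple[str, ...]
    global_values: dict[str, dict[str, np.ndarray]]   # type -> metric -> (n_subjects,)
    nodal_values: dict[str, dict[str, np.ndarray]]    # type -> metric -> (n_subjects, N)
    global_tests: dict[tuple[str, str], dict[str, tuple[float, float]]]  # (a,b) -> metric -> (t, p)
    nodal_q: dict[tuple[str, str], dict[str, np.ndarray]]  # BH q-values per node
    normalize: str


def _normalize(matrix: np.ndarray, mode: str) -> np.ndarray:
    if mode == "none":
        return matrix
    if mode == "max":
        top = matrix.max()
        return matrix / top if top > 0 else matrix
    if mode == "sum":
        total = matrix.sum()
        return matrix / total if total > 0 else matrix
    raise ValidationError(f"unknown normalize mode {mode!r}")


def subject_metrics(matrix: np.ndarray) -> dict[str, float | np.ndarray]:
    """All global and nodal metrics of one nonnegative weighted matrix."""
    bet_vec, bet_mean = betweenness(matrix)
    try:
        _, q, contrib = modularity_partition(matrix)
    except ValidationError:
        q, contrib = 0.0, np.zeros(matrix.shape[0])
    return {
        "global_efficiency": global_efficiency(matrix),
        "mean_betweenness": bet_mean,
        "modularity_Q": q,
        "nodal_efficiency": nodal_efficiency(matrix),
        "local_efficiency": local_efficiency(matrix),
        "betweenness": bet_vec,
        "nodal_modularity_contribution": contrib,
    }


def compare_metrics(
    cohort: Sequence[SubjectConnectome],
    usfc_list: Sequence[USFCMatrix],
    normalize: str = "max",
    alpha: float = 0.05,
) -> MetricsComparison:
    """Compute all metrics per subject for SC, |FC|, USFC and compare types.

    Matrices are normalized per subject (default: divided by their maximum)
    so comparisons reflect topology rather than the very different native
    scales of the three connectivity types.  Global metrics get paired
    two-sided t-tests per type pair; nodal metrics additionally get per-node
    paired t-tests BH-corrected across nodes.
    """
    if len(cohort) < 2:
        raise ValidationError("metric comparison needs at least 2 subjects")
    if len(cohort) != len(usfc_list):
        raise ValidationError("cohort and USFC list lengths differ")
    mats = {
        "SC": [_normalize(s.sc.values, normalize) for s in cohort],
        "FC": [_normalize(np.abs(s.fc.values), normalize) for s in cohort],
        "USFC": [_normalize(np.abs(u.values), normalize) for u in usfc_list],
    }
    global_values: dict[str, dict[str, np.ndarray]] = {}
    nodal_values: dict[str, dict[str, np.ndarray]] = {}
    for ctype, matrices in mats.items():
        per_subject = [subject_metrics(m) for m in matrices]
        global_values[ctype] = {
            metric: np.array([ms[metric] for ms in per_subject]) for metric in GLOBAL_METRICS
        }
        nodal_values[ctype] = {
            metric: np.stack([ms[metric] for ms in per_subject]) for metric in NODAL_METRICS
        }

    global_tests: dict[tuple[str, str], dict[str, tuple[float, float]]] = {}
    nodal_q: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for a, b in (("USFC", "SC"), ("USFC", "FC"), ("SC", "FC")):
        global_tests[(a, b)] = {}
        nodal_q[(a, b)] = {}
        for metric in GLOBAL_METRICS:
            diff = global_values[a][metric] - global_values[b][metric]
            if np.allclose(diff, 0):
                global_tests[(a, b)][metric] = (0.0, 1.0)
            else:
                res = sps.ttest_rel(global_values[a][metric], global_values[b][metric])
                global_tests[(a, b)][metric] = (float(res.statistic), float(res.pvalue))
        for metric in NODAL_METRICS:
            va, vb = nodal_values[a][metric], nodal_values[b][metric]
            pvals = np.ones(va.shape[1])
            for i in range(va.shape[1]):
                if np.allclose(va[:, i], vb[:, i]):
                    continue
                pvals[i] = sps.ttest_rel(va[:, i], vb[:, i]).pvalue
            pvals = np.where(np.isnan(pvals), 1.0, pvals)
            _, q, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
            nodal_q[(a, b)][metric] = q

    return MetricsComparison(
        types=CONNECTIVITY_TYPES,
        global_values=global_values,
        nodal_values=nodal_values,
        global_tests=global_tests,
        nodal_q=nodal_q,
        normalize=normalize,
    )
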