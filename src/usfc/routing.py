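"""Efficient-pathway search: hop-limited minimum-cost routing over structural edges.

The routing model treats the structural connectome as a road system.  Each
step between adjacent regions costs Euclidean centroid distance divided by
structural connectivity strength (``D / SC``); an absent structural edge
(``SC = 0``) is inadmissible (infinite cost).  The most efficient pathway
(EP) for a region pair is the simple path of at most ``max_steps`` edges
(default 4) minimizing the summed step costs:

    EP(i, j) = argmin over routes  sum_k  D(n_k, n_{k+1}) / SC(n_k, n_{k+1})

Ties are broken deterministically: fewer steps first, then the
lexicographically smallest node-index sequence.

The search is an exact hop-layered relaxation keeping the best state per
(node, hop count) — optimal substructure only holds per hop layer, so an
unconstrained shortest path with more than ``max_steps`` edges is correctly
passed over in favor of the best admissible route.  ``brute_force_pathway``
is an independent exhaustive oracle for small graphs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps
from scipy.spatial.distance import cdist
from statsmodels.stats.multitest import multipletests

from .io import ConnMatrix, RegionAtlas, ValidationError

DEFAULT_MAX_STEPS = 4

_COST_TOL = 1e-9


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectConnectome:
    """One subject's SC and FC matrices plus an optional FC-significance mask."""

    subject_id: str
    sc: ConnMatrix
    fc: ConnMatrix
    fc_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.sc.kind != "SC" or self.fc.kind != "FC":
            raise ValidationError("SubjectConnectome requires kinds SC and FC")
        if self.sc.n != self.fc.n:
            raise ValidationError("SC and FC dimensions differ")
        if self.fc_mask is not None:
            mask = np.asarray(self.fc_mask, dtype=bool)
            if mask.shape != self.fc.values.shape:
                raise ValidationError("fc_mask shape mismatch")
            if not np.array_equal(mask, mask.T) or np.any(np.diagonal(mask)):
                raise ValidationError("fc_mask must be symmetric with false diagonal")
            object.__setattr__(self, "fc_mask", mask)

    @property
    def n(self) -> int:
        return self.sc.n


@dataclass(frozen=True)
class Route:
    """A simple path from source to target with its summed D/SC cost."""

    pair: tuple[int, int]          # unordered, stored sorted
    nodes: tuple[int, ...]         # ordered source -> target
    n_steps: int
    total_cost: float

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValidationError("route must be a simple path")
        if self.n_steps != len(self.nodes) - 1 or self.n_steps < 1:
            raise ValidationError("n_steps inconsistent with node sequence")
        if tuple(sorted((self.nodes[0], self.nodes[-1]))) != self.pair:
            raise ValidationError("pair does not match route endpoints")
        if not (self.total_cost > 0 and math.isfinite(self.total_cost)):
            raise ValidationError("total_cost must be positive and finite")

    @property
    def edges(self) -> tuple[tuple[int, int], ...]:
        return tuple(zip(self.nodes[:-1], self.nodes[1:]))


@dataclass(frozen=True)
class RouteTable:
    """All routed pairs of one subject plus the pairs no admissible route reached."""

    subject_id: str
    routes: dict[tuple[int, int], Route]
    unroutable: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        overlap = set(self.routes) & set(self.unroutable)
        if overlap:
            raise ValidationError(f"pairs both routed and unroutable: {sorted(overlap)}")

    @property
    def n_routed(self) -> int:
        return len(self.routes)


# ---------------------------------------------------------------------------
# Geometry and edge costs
# ---------------------------------------------------------------------------

def euclidean_distances(atlas: RegionAtlas) -> ConnMatrix:
    """Straight-line centroid distances in mm (the template distance map)."""
    d = cdist(atlas.centroids, atlas.centroids)
    d = (d + d.T) / 2.0  # exact symmetry
    off = ~np.eye(atlas.n_regions, dtype=bool)
    if np.any(d[off] <= 0):
        i, j = np.argwhere((d <= 0) & off)[0]
        raise ValidationError(
            f"coincident centroids for regions {atlas.labels[i]!r} and {atlas.labels[j]!r}"
        )
    return ConnMatrix(values=d, kind="DIST", labels=atlas.labels)


def edge_cost(dist: float, sc_weight: float) -> float:
    """Cost of one step: distance / SC strength; +inf when the edge is absent."""
    if dist <= 0:
        raise ValueError(f"distance must be positive, got {dist}")
    if sc_weight < 0:
        raise ValueError(f"SC weight must be nonnegative, got {sc_weight}")
    if sc_weight == 0:
        return math.inf
    return dist / sc_weight


def _as_values(m: ConnMatrix | np.ndarray) -> np.ndarray:
    return m.values if isinstance(m, ConnMatrix) else np.asarray(m, dtype=float)


def _cost_adjacency(D: np.ndarray, SC: np.ndarray) -> list[list[tuple[int, float]]]:
    """Adjacency lists of (neighbor, step cost) over edges with SC > 0."""
    n = D.shape[0]
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    ii, jj = np.nonzero(SC > 0)
    costs = D[ii, jj] / SC[ii, jj]
    for u, v, c in zip(ii.tolist(), jj.tolist(), costs.tolist()):
        if u != v:
            adj[u].append((v, c))
    return adj


# ---------------------------------------------------------------------------
# Search
# ---------------------------------------------------------------------------

def _single_source_best(
    adj: list[list[tuple[int, float]]], source: int, max_steps: int
) -> dict[int, tuple[float, tuple[int, ...]]]:
    """Best (cost, node sequence) from ``source`` to every reachable node.

    Hop-layered relaxation: ``layers[h][v]`` holds the best simple path of
    exactly ``h`` edges ending at ``v``, compared by (cost, sequence).  The
    final answer per target minimizes (cost, n_steps, sequence) across layers,
    implementing the documented tie-break.
    """
    layers: list[dict[int, tuple[float, tuple[int, ...]]]] = [
        {} for _ in range(max_steps + 1)
    ]
    layers[0][source] = (0.0, (source,))
    for h in range(1, max_steps + 1):
        prev, cur = layers[h - 1], layers[h]
        for u, (cost_u, path_u) in prev.items():
            for v, w in adj[u]:
                if v in path_u:
                    continue
                cand = (cost_u + w, path_u + (v,))
                old = cur.get(v)
                if old is None or cand < old:
                    cur[v] = cand
    best: dict[int, tuple[float, tuple[int, ...]]] = {}
    for h in range(1, max_steps + 1):
        for v, (cost, path) in layers[h].items():
            if v == source:
                continue
            old = best.get(v)
            if old is None or (cost, len(path), path) < (old[0], len(old[1]), old[1]):
                best[v] = (cost, path)
    return best


def find_efficient_pathway(
    D: ConnMatrix | np.ndarray,
    SC: ConnMatrix | np.ndarray,
    source: int,
    target: int,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> Optional[Route]:
    """Minimum-cost simple path of at most ``max_steps`` edges, or None."""
    if source == target:
        raise ValueError("source and target must differ")
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    Dv, SCv = _as_values(D), _as_values(SC)
    adj = _cost_adjacency(Dv, SCv)
    best = _single_source_best(adj, source, max_steps)
    hit = best.get(target)
    if hit is None:
        return None
    cost, path = hit
    return Route(
        pair=tuple(sorted((source, target))),
        nodes=path,
        n_steps=len(path) - 1,
        total_cost=cost,
    )


def brute_force_pathway(
    D: ConnMatrix | np.ndarray,
    SC: ConnMatrix | np.ndarray,
    source: int,
    target: int,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> Optional[Route]:
    """Exhaustive oracle: enumerate every simple path of <= ``max_steps`` edges.

    Intended for small graphs only (N <= 14); applies the same tie-break rule
    as :func:`find_efficient_pathway` so results are comparable exactly.
    """
    if source == target:
        raise ValueError("source and target must differ")
    Dv, SCv = _as_values(D), _as_values(SC)
    n = Dv.shape[0]
    if n > 14:
        raise ValueError(f"brute force guarded to N <= 14, got N = {n}")
    adj = _cost_adjacency(Dv, SCv)
    best: Optional[tuple[float, int, tuple[int, ...]]] = None

    def dfs(node: int, path: tuple[int, ...], cost: float) -> None:
        nonlocal best
        if node == target:
            key = (cost, len(path) - 1, path)
            if best is None or key < best:
                best = key
            return
        if len(path) - 1 >= max_steps:
            return
        for v, w in adj[node]:
            if v in path:
                continue
            dfs(v, path + (v,), cost + w)

    dfs(source, (source,), 0.0)
    if best is None:
        return None
    cost, n_steps, path = best
    return Route(
        pair=tuple(sorted((source, target))),
        nodes=path,
        n_steps=n_steps,
        total_cost=cost,
    )


# ---------------------------------------------------------------------------
# Whole-subject routing
# ---------------------------------------------------------------------------

def select_pairs(subject: SubjectConnectome, fc_policy: str) -> list[tuple[int, int]]:
    """Unordered pairs to route: masked (significant FC) or all nonzero FC."""
    n = subject.n
    if fc_policy == "masked":
        if subject.fc_mask is None:
            raise ValueError("fc_policy='masked' requires a fc_mask on the subject")
        sel = subject.fc_mask
    elif fc_policy == "all_nonzero":
        sel = subject.fc.values != 0
    else:
        raise ValueError(f"unknown fc_policy {fc_policy!r}")
    iu, ju = np.triu_indices(n, k=1)
    keep = sel[iu, ju]
    return list(zip(iu[keep].tolist(), ju[keep].tolist()))


def route_all_pairs(
    subject: SubjectConnectome,
    D: ConnMatrix | np.ndarray,
    max_steps: int = DEFAULT_MAX_STEPS,
    fc_policy: str = "all_nonzero",
) -> RouteTable:
    """Route every selected functional connection of one subject.

    Pairs whose cheapest admissible route does not exist within ``max_steps``
    edges are recorded as unroutable.
    """
    Dv, SCv = _as_values(D), _as_values(subject.sc)
    pairs = select_pairs(subject, fc_policy)
    adj = _cost_adjacency(Dv, SCv)
    by_source: dict[int, list[int]] = {}
    for i, j in pairs:
        by_source.setdefault(i, []).append(j)
    routes: dict[tuple[int, int], Route] = {}
    unroutable: set[tuple[int, int]] = set()
    for src, targets in by_source.items():
        best = _single_source_best(adj, src, max_steps)
        for tgt in targets:
            hit = best.get(tgt)
            if hit is None:
                unroutable.add((src, tgt))
            else:
                cost, path = hit
                routes[(src, tgt)] = Route(
                    pair=(src, tgt), nodes=path, n_steps=len(path) - 1, total_cost=cost
                )
    return RouteTable(
        subject_id=subject.subject_id, routes=routes, unroutable=frozenset(unroutable)
    )


# ---------------------------------------------------------------------------
# FC significance helper
# ---------------------------------------------------------------------------

def fc_significance_mask(
    fc: ConnMatrix | np.ndarray, n_timepoints: int, alpha: float = 0.05
) -> np.ndarray:
    """Per-subject significance mask for Pearson FC values.

    Transforms each correlation to a t statistic with ``n_timepoints - 2``
    degrees of freedom, then applies Benjamini-Hochberg FDR at ``alpha``
    across the upper-triangle pairs.
    """
    r = _as_values(fc)
    n = r.shape[0]
    if n_timepoints < 4:
        raise ValueError("need at least 4 time points for a correlation test")
    iu, ju = np.triu_indices(n, k=1)
    rv = np.clip(r[iu, ju], -1 + 1e-15, 1 - 1e-15)
    df = n_timepoints - 2
    t = rv * np.sqrt(df / (1.0 - rv**2))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    reject, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    mask = np.zeros((n, n), dtype=bool)
    mask[iu, ju] = reject
    return mask | mask.T
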