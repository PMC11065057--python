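"""Step-stratified SC-FC coupling along consistent traffic routes.

Routes are first reduced to those consistent across the cohort: a pair is
kept only when its modal (most frequent) exact node sequence occurs in more
than a configurable fraction of subjects (default: over 50%).  For every
consistent route, the structural side is the arithmetic mean SC over the
route's consecutive edges (averaged across subjects) and the functional side
is the group-mean FC of the pair.  Routes are then split by the sign of
group FC and grouped by step count (1-4), and Spearman's rank correlation
between route-mean SC and FC is computed per group.

Small groups are common at the 3- and 4-step level, so p-values switch to an
exact permutation computation below n = 10 and use the usual t approximation
otherwise.
"""

from __future__ import annotations

import itertools
import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .io import ConnMatrix, ValidationError
from .routing import RouteTable, SubjectConnectome

MIN_GROUP_N = 3
_EXACT_PERM_MAX_N = 9  # n! permutations enumerated up to here


@dataclass(frozen=True)
class ConsistentRoute:
    """A route shared (exactly) by the majority of the cohort."""

    pair: tuple[int, int]
    modal_nodes: tuple[int, ...]
    n_steps: int
    support: float            # fraction of subjects with exactly this sequence
    group_fc: float
    group_mean_sc: float

    def __post_init__(self) -> None:
        if self.n_steps != len(self.modal_nodes) - 1:
            raise ValidationError("n_steps inconsistent with modal sequence")


@dataclass(frozen=True)
class CouplingCell:
    n_routes: int
    rho: Optional[float]
    p_value: Optional[float]


@dataclass(frozen=True)
class CouplingResult:
    """Spearman rho per (step, FC sign) group plus the route-count table."""

    cells: dict[tuple[int, str], CouplingCell]  # key: (n_steps, '+'|'-')
    n_consistent: int
    max_steps: int

    def counts(self) -> dict[tuple[int, str], int]:
        return {k: c.n_routes for k, c in self.cells.items()}


# ---------------------------------------------------------------------------
# Consistency across subjects
# ---------------------------------------------------------------------------

def route_mean_sc(route_nodes: Sequence[int], sc: ConnMatrix | np.ndarray) -> float:
    """Arithmetic mean of SC over the route's consecutive-node edges."""
    scv = sc.values if isinstance(sc, ConnMatrix) else np.asarray(sc, dtype=float)
    vals = []
    for a, b in zip(route_nodes[:-1], route_nodes[1:]):
        w = scv[a, b]
        if w <= 0:
            raise ValidationError(f"route edge ({a}, {b}) absent from SC")
        vals.append(w)
    return float(np.mean(vals))


def modal_routes(
    route_tables: Sequence[RouteTable],
    subjects: Sequence[SubjectConnectome],
    threshold: float = 0.5,
    identity: str = "sequence",
) -> list[ConsistentRoute]:
    """Consistent routes: the modal route per pair, kept above the threshold.

    ``identity='sequence'`` (default) requires the exact node sequence to
    repeat; ``identity='steps'`` only requires the same step count (the
    modal sequence among routes of the modal step count is then reported).
    Support must strictly exceed ``threshold`` (over 50% at the default);
    modal ties drop the pair with a warning.
    """
    if len(route_tables) < 2:
        raise ValidationError("consistency analysis needs at least 2 subjects")
    if len(route_tables) != len(subjects):
        raise ValidationError("route tables and subjects must align")
    if identity not in ("sequence", "steps"):
        raise ValidationError(f"unknown route identity {identity!r}")
    n_subjects = len(route_tables)
    by_pair: dict[tuple[int, int], list[tuple[int, ...]]] = {}
    for table in route_tables:
        for pair, route in table.routes.items():
            by_pair.setdefault(pair, []).append(route.nodes)

    out: list[ConsistentRoute] = []
    n_tied = 0
    for pair, seqs in sorted(by_pair.items()):
        keys = seqs if identity == "sequence" else [len(s) - 1 for s in seqs]
        counts = Counter(keys)
        (modal_key, freq), *rest = counts.most_common()
        if rest and rest[0][1] == freq:
            n_tied += 1
            continue
        support = freq / n_subjects
        if support <= threshold:
            continue
        if identity == "sequence":
            modal_seq = modal_key
        else:
            modal_seq = Counter(
                s for s in seqs if len(s) - 1 == modal_key
            ).most_common(1)[0][0]

        fc_vals = [s.fc.values[pair] for s in subjects]
        sc_means = []
        for s in subjects:
            try:
                sc_means.append(route_mean_sc(modal_seq, s.sc))
            except ValidationError:
                continue  # subject lacks an edge of the modal route
        if not sc_means:
            warnings.warn(
                f"modal route for pair {pair} absent from every subject's SC; dropped",
                stacklevel=2,
            )
            continue
        out.append(
            ConsistentRoute(
                pair=pair,
                modal_nodes=tuple(modal_seq),
                n_steps=len(modal_seq) - 1,
                support=support,
                group_fc=float(np.mean(fc_vals)),
                group_mean_sc=float(np.mean(sc_means)),
            )
        )
    if n_tied:
        warnings.warn(f"{n_tied} pairs dropped due to modal-route ties", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# Spearman correlation with exact small-sample p
# ---------------------------------------------------------------------------

def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with a two-sided p: exact permutation below n = 10."""
    n = x.size
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return math.nan, math.nan
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n > _EXACT_PERM_MAX_N:
        return tuple(sps.spearmanr(x, y))  # t approximation
    # exact: enumerate all n! pairings of the rank vectors
    perms = np.array(list(itertools.permutations(ry)))
    rx_c = rx - rx.mean()
    rhos = (perms - ry.mean()) @ rx_c / (n * sx * sy)
    p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    return rho, p


def coupling_by_step(
    consistent: Sequence[ConsistentRoute], max_steps: int = 4
) -> CouplingResult:
    """Per (step count, FC sign) group: route count and Spearman rho/p.

    Routes with exactly zero group FC belong to neither sign and are
    excluded (logged); groups with fewer than 3 routes report their count
    but no correlation.
    """
    n_zero = sum(1 for r in consistent if r.group_fc == 0)
    if n_zero:
        warnings.warn(f"{n_zero} routes with zero group FC excluded", stacklevel=2)
    cells: dict[tuple[int, str], CouplingCell] = {}
    for step in range(1, max_steps + 1):
        for sign in ("+", "-"):
            members = [
                r
                for r in consistent
                if r.n_steps == step
                and r.group_fc != 0
                and (r.group_fc > 0) == (sign == "+")
            ]
            if len(members) < MIN_GROUP_N:
                cells[(step, sign)] = CouplingCell(len(members), None, None)
                continue
            sc_vals = np.array([r.group_mean_sc for r in members])
            fc_vals = np.array([r.group_fc for r in members])
            rho, p = _spearman(sc_vals, fc_vals)
            if math.isnan(rho):
                cells[(step, sign)] = CouplingCell(len(members), None, None)
            else:
                cells[(step, sign)] = CouplingCell(len(members), rho, p)
    return CouplingResult(
        cells=cells,
        n_consistent=sum(1 for r in consistent if r.group_fc != 0),
        max_steps=max_steps,
    )
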