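"""Synthetic connectome cohorts with known ground truth.

Emulates the statistical structure the traffic-map analysis assumes, without
any biophysical simulation:

* an atlas of ~90 regions with 3D centroids inside a brain-sized ellipsoid
  (~140 x 180 x 120 mm) and spatially contiguous network clusters, the first
  of which is a midline "corridor" network hosting the planted backbone;
* sparse modular structural connectivity (SC) in (0, 1]: connection
  probability decays with distance and is boosted within networks; a planted
  high-SC backbone chain runs anterior-to-posterior through the corridor
  network;
* functional connectivity (FC) tied to the cheapest structural route on the
  group-mean SC: pairs with cheap routes get strong positive FC, while pairs
  between designated network blocks get negative FC whose magnitude increases
  with the mean SC along their cheapest route (so stronger negative FC sits
  on structurally stronger routes);
* per-subject matrices are the group mean plus symmetric Gaussian noise,
  clipped to the valid range.  SC noise is applied only on the support of the
  group-mean SC so per-subject structural topology stays fixed; additive
  noise on true zeros would densify the graph with near-zero edges and break
  the configured density.

Randomness comes from two rng streams derived from the config seed — one for
the atlas, one for the cohort — with a fixed draw order (centroids, cluster
seeding, SC support, SC weights, negative-block direct edges, then
per-subject SC/FC noise in subject order), so identical configs give
bitwise-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import ConnMatrix, RegionAtlas, ValidationError
from .routing import (
    SubjectConnectome,
    _cost_adjacency,
    _single_source_best,
    euclidean_distances,
)

# Ellipsoid semi-axes (mm): left-right, anterior-posterior, inferior-superior
_SEMI_AXES = (70.0, 90.0, 60.0)

# Distance scale (mm) of the connection-probability decay and weight decay
_DECAY_MM = 120.0
_WITHIN_NETWORK_BOOST = 4.0

# Relay-hub connectivity of backbone regions: probability and weight of
# direct spokes from any region to a corridor region
_HUB_SPOKE_PROB = 1.0
_HUB_SPOKE_WEIGHT = 0.45

# Ceiling for ordinary (non-hub, non-backbone) SC weights.  Matching the hub
# spoke weight keeps emergent relay regions from out-competing the corridor:
# no ordinary edge is ever a better on-ramp than a direct spoke.
_ORDINARY_WEIGHT_MAX = 0.45

# FC model constants: positive FC decays with route cost, negative FC grows
# in magnitude with route-mean SC
_FC_COST_SCALE = 200.0
_FC_POS_BASE, _FC_POS_GAIN = 0.05, 1.6
_FC_NEG_BASE, _FC_NEG_GAIN = 0.10, 0.60
_FC_UNROUTED_POS = 0.05
_FC_UNROUTED_NEG = -0.05

# A fraction of anti-correlated block pairs get a strong direct SC edge, so
# the cohort contains single-step routes under negative FC whose strength
# varies — the planted "stronger SC under stronger negative FC" relation
_NEG_DIRECT_PROB = 0.10
_NEG_DIRECT_WMIN, _NEG_DIRECT_WMAX = 0.35, 0.70


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic cohort."""

    n_regions: int = 90
    n_networks: int = 8
    n_subjects: int = 20
    sc_density: float = 0.15
    backbone: Optional[tuple[int, ...]] = None  # 0-based region indices; None = auto
    backbone_strength: float = 0.9
    noise_sd: float = 0.05
    negfc_block_pairs: Optional[tuple[tuple[str, str], ...]] = None  # None = auto
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 4:
            raise ValidationError("n_regions must be >= 4")
        if not (1 <= self.n_networks <= self.n_regions):
            raise ValidationError("need 1 <= n_networks <= n_regions")
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if not (0 < self.sc_density <= 1):
            raise ValidationError("sc_density must lie in (0, 1]")
        if not (0 < self.backbone_strength <= 1):
            raise ValidationError("backbone_strength must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        if self.backbone is not None:
            bb = tuple(int(b) for b in self.backbone)
            if len(bb) < 2 or len(set(bb)) != len(bb):
                raise ValidationError("backbone must be a simple path of >= 2 regions")
            if any(b < 0 or b >= self.n_regions for b in bb):
                raise ValidationError("backbone nodes outside the region set")
            object.__setattr__(self, "backbone", bb)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    backbone_edges: frozenset[tuple[int, int]]
    planted_routes: dict[tuple[int, int], tuple[int, ...]]
    fc_sign_map: dict[tuple[int, int], str]  # '+' or '-'


def _corridor_size(n_regions: int) -> int:
    # 12 of 90 at full scale, scaled down proportionally for small test atlases
    return min(12, max(2, n_regions // 8 + 1))


def generate_atlas(config: SynthConfig) -> RegionAtlas:
    """Sample centroids in the ellipsoid and assign contiguous networks.

    Network ``N1`` is the midline corridor: the regions with the smallest
    left-right offset, spanning anterior to posterior.  Remaining regions are
    clustered into ``n_networks - 1`` contiguous groups via farthest-point
    seeding and nearest-seed assignment.
    """
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_regions
    semi = np.asarray(_SEMI_AXES)
    pts = np.empty((0, 3))
    while pts.shape[0] < n:  # rejection-sample uniform points in the ellipsoid
        cand = rng.uniform(-1, 1, size=(4 * n, 3))
        cand = cand[np.sum(cand**2, axis=1) <= 1.0]
        pts = np.vstack([pts, cand * semi])
    centroids = pts[:n]

    networks = np.empty(n, dtype=object)
    if config.n_networks == 1:
        networks[:] = "N1"
    else:
        n_corr = min(_corridor_size(n), n - (config.n_networks - 1))
        # corridor = regions nearest the anterior-posterior midline axis within
        # the central band, so the y-ordered backbone chain is a short sequence
        # of hops and traffic from both poles funnels through its terminal edges
        axis_dist = np.hypot(centroids[:, 0], centroids[:, 2])
        central = np.abs(centroids[:, 1]) <= 0.65 * semi[1]
        if central.sum() >= n_corr:
            axis_dist = np.where(central, axis_dist, np.inf)
        corridor = np.argsort(axis_dist, kind="stable")[:n_corr]
        networks[corridor] = "N1"
        rest = np.setdiff1d(np.arange(n), corridor)
        k = config.n_networks - 1
        # farthest-point seeding over the remaining regions
        seeds = [rest[int(rng.integers(len(rest)))]]
        for _ in range(k - 1):
            d2 = np.min(
                [np.sum((centroids[rest] - centroids[s]) ** 2, axis=1) for s in seeds],
                axis=0,
            )
            seeds.append(rest[int(np.argmax(d2))])
        seed_pts = centroids[seeds]
        assign = np.argmin(
            np.sum((centroids[rest, None, :] - seed_pts[None, :, :]) ** 2, axis=2), axis=1
        )
        for idx, a in zip(rest, assign):
            networks[idx] = f"N{a + 2}"

    return RegionAtlas(
        region_ids=tuple(range(1, n + 1)),
        labels=tuple(f"R{i:03d}" for i in range(1, n + 1)),
        centroids=centroids,
        networks=tuple(networks),
    )


def default_backbone(atlas: RegionAtlas) -> tuple[int, ...]:
    """Corridor-network regions ordered anterior to posterior (by y)."""
    host = "N1" if "N1" in set(atlas.networks) else atlas.networks[0]
    corridor = atlas.regions_in_network(host)
    order = corridor[np.argsort(atlas.centroids[corridor, 1], kind="stable")]
    return tuple(int(i) for i in order)


def default_negfc_pairs(atlas: RegionAtlas) -> tuple[tuple[str, str], ...]:
    """Two spatially separated non-corridor network pairs (fewer if unavailable)."""
    nets = [x for x in atlas.network_names if x != "N1"]
    nets = sorted(nets, key=lambda s: int(s[1:]))
    if len(nets) >= 6:
        return ((nets[0], nets[3]), (nets[1], nets[4]))
    if len(nets) >= 2:
        return ((nets[0], nets[1]),)
    names = sorted(atlas.network_names)
    return ((names[0], names[0]),) if names else ()


def _symmetric_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    noise = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    draws = rng.normal(0.0, sd, size=iu.size) if sd > 0 else np.zeros(iu.size)
    noise[iu, ju] = draws
    noise[ju, iu] = draws
    return noise


def generate_cohort(
    config: SynthConfig, atlas: RegionAtlas
) -> tuple[list[SubjectConnectome], GroundTruth]:
    """Generate per-subject SC/FC matrices plus the planted ground truth."""
    n = atlas.n_regions
    if n != config.n_regions:
        raise ValidationError("atlas size does not match config.n_regions")
    rng = np.random.default_rng([config.seed, 1])
    D = euclidean_distances(atlas).values

    backbone = config.backbone if config.backbone is not None else default_backbone(atlas)
    if any(b >= n for b in backbone):
        raise ValidationError("backbone nodes outside atlas")
    backbone_edges = frozenset(
        tuple(sorted(e)) for e in zip(backbone[:-1], backbone[1:])
    )

    # --- group-mean SC: distance-decaying support, densified within networks
    nets = np.asarray(atlas.networks)
    same_net = nets[:, None] == nets[None, :]
    decay = np.exp(-D / _DECAY_MM)
    raw_p = decay * np.where(same_net, _WITHIN_NETWORK_BOOST, 1.0)
    iu, ju = np.triu_indices(n, k=1)
    raw_p *= config.sc_density / np.mean(raw_p[iu, ju])
    # backbone regions are relay hubs (thalamus-like): widespread moderate
    # connectivity, so distant regions reach the corridor by a direct spoke
    is_bb = np.zeros(n, dtype=bool)
    is_bb[list(backbone)] = True
    hub_pair = is_bb[:, None] | is_bb[None, :]
    prob = np.clip(np.where(hub_pair, np.maximum(raw_p, _HUB_SPOKE_PROB), raw_p), 0.0, 1.0)
    support = np.zeros((n, n), dtype=bool)
    support[iu, ju] = rng.uniform(size=iu.size) < prob[iu, ju]
    support = support | support.T

    # ordinary weights span (0.05, _ORDINARY_WEIGHT_MAX) without piling up at
    # the ceiling, so SC strength keeps a usable dynamic range
    ordinary = 0.10 + (_ORDINARY_WEIGHT_MAX - 0.12) * decay
    weights = np.clip(
        np.where(hub_pair, _HUB_SPOKE_WEIGHT, ordinary)
        + _symmetric_noise(rng, n, 0.05),
        0.05,
        np.where(hub_pair, min(0.8, config.backbone_strength), _ORDINARY_WEIGHT_MAX),
    )
    mean_sc = np.where(support, weights, 0.0)

    # --- anti-correlated network blocks (negative-FC pairs)
    neg_pairs = (
        config.negfc_block_pairs
        if config.negfc_block_pairs is not None
        else default_negfc_pairs(atlas)
    )
    neg_block = np.zeros((n, n), dtype=bool)
    for net_a, net_b in neg_pairs:
        ia = atlas.regions_in_network(net_a)
        ib = atlas.regions_in_network(net_b)
        if ia.size == 0 or ib.size == 0:
            raise ValidationError(f"negfc network pair ({net_a}, {net_b}) not in atlas")
        neg_block[np.ix_(ia, ib)] = True
        neg_block[np.ix_(ib, ia)] = True
    np.fill_diagonal(neg_block, False)

    # plant strong, variable direct SC under a fraction of negative-FC pairs
    blk = neg_block[iu, ju] & ~hub_pair[iu, ju]
    chosen = blk & (rng.uniform(size=iu.size) < _NEG_DIRECT_PROB)
    direct_w = rng.uniform(_NEG_DIRECT_WMIN, _NEG_DIRECT_WMAX, size=int(chosen.sum()))
    ci, cj = iu[chosen], ju[chosen]
    support[ci, cj] = support[cj, ci] = True
    mean_sc[ci, cj] = mean_sc[cj, ci] = direct_w

    for a, b in backbone_edges:
        support[a, b] = support[b, a] = True
        mean_sc[a, b] = mean_sc[b, a] = config.backbone_strength
    np.fill_diagonal(mean_sc, 0.0)
    np.fill_diagonal(support, False)

    # --- cheapest routes on the group-mean SC define the FC structure
    adj = _cost_adjacency(D, mean_sc)
    planted_routes: dict[tuple[int, int], tuple[int, ...]] = {}
    route_cost = np.full((n, n), np.inf)
    route_mean_sc = np.zeros((n, n))
    for src in range(n):
        best = _single_source_best(adj, src, max_steps=4)
        for tgt, (cost, path) in best.items():
            if tgt <= src:
                continue
            planted_routes[(src, tgt)] = path
            route_cost[src, tgt] = route_cost[tgt, src] = cost
            sc_vals = [mean_sc[a, b] for a, b in zip(path[:-1], path[1:])]
            route_mean_sc[src, tgt] = route_mean_sc[tgt, src] = float(np.mean(sc_vals))

    # --- group-mean FC: sign by network block, magnitude from the route
    routed = np.isfinite(route_cost)
    pos_fc = np.where(
        routed,
        _FC_POS_BASE
        + _FC_POS_GAIN * np.exp(-route_cost / _FC_COST_SCALE) * route_mean_sc,
        _FC_UNROUTED_POS,
    )
    neg_fc = np.where(
        routed,
        -(_FC_NEG_BASE + _FC_NEG_GAIN * route_mean_sc),
        _FC_UNROUTED_NEG,
    )
    mean_fc = np.clip(np.where(neg_block, neg_fc, pos_fc), -0.95, 0.95)
    np.fill_diagonal(mean_fc, 0.0)

    fc_sign_map = {
        (int(i), int(j)): "-" if neg_block[i, j] else "+"
        for i, j in zip(iu.tolist(), ju.tolist())
    }

    # --- subjects: mean + symmetric noise, clipped; SC noise on support only
    subjects: list[SubjectConnectome] = []
    for s in range(config.n_subjects):
        sc_s = np.clip(mean_sc + _symmetric_noise(rng, n, config.noise_sd), 0.0, 1.0)
        sc_s = np.where(support, np.maximum(sc_s, 1e-6), 0.0)  # keep support intact
        fc_s = np.clip(mean_fc + _symmetric_noise(rng, n, config.noise_sd), -1.0, 1.0)
        np.fill_diagonal(sc_s, 0.0)
        np.fill_diagonal(fc_s, 0.0)
        subjects.append(
            SubjectConnectome(
                subject_id=f"sub-{s + 1:03d}",
                sc=ConnMatrix(values=sc_s, kind="SC", labels=atlas.labels),
                fc=ConnMatrix(values=fc_s, kind="FC", labels=atlas.labels),
            )
        )

    truth = GroundTruth(
        backbone_edges=backbone_edges,
        planted_routes=planted_routes,
        fc_sign_map=fc_sign_map,
    )
    return subjects, truth


def generate_dataset(
    config: SynthConfig,
) -> tuple[RegionAtlas, list[SubjectConnectome], GroundTruth]:
    """Convenience: atlas + cohort in one call."""
    atlas = generate_atlas(config)
    subjects, truth = generate_cohort(config, atlas)
    return atlas, subjects, truth
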