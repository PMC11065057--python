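"""Efficient-pathway search: distances, costs, hop-limited optimality."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import usfc
from usfc.io import ConnMatrix, RegionAtlas, ValidationError
from usfc.routing import (
    SubjectConnectome,
    brute_force_pathway,
    edge_cost,
    euclidean_distances,
    fc_significance_mask,
    find_efficient_pathway,
    route_all_pairs,
)

from conftest import make_random_problem


class TestEuclideanDistances:
    def test_three_four_five_triangle(self):
        atlas = RegionAtlas(
            region_ids=(1, 2),
            labels=("A", "B"),
            centroids=np.array([[0.0, 0, 0], [3, 4, 0]]),
            networks=("n", "n"),
        )
        d = euclidean_distances(atlas)
        assert d.values[0, 1] == pytest.approx(5.0)

    def test_symmetric_zero_diagonal_full_scale(self):
        atlas = usfc.generate_atlas(usfc.SynthConfig(seed=2))
        d = euclidean_distances(atlas).values
        assert np.array_equal(d, d.T)
        assert np.all(np.diagonal(d) == 0)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-50, 50, size=(6, 3))
        perm = rng.permutation(6)
        atlas_a = RegionAtlas(
            region_ids=tuple(range(1, 7)),
            labels=tuple(f"R{i}" for i in range(6)),
            centroids=pts,
            networks=("n",) * 6,
        )
        atlas_b = RegionAtlas(
            region_ids=tuple(range(1, 7)),
            labels=tuple(f"R{i}" for i in perm),
            centroids=pts[perm],
            networks=("n",) * 6,
        )
        da = euclidean_distances(atlas_a).values
        db = euclidean_distances(atlas_b).values
        np.testing.assert_allclose(db, da[np.ix_(perm, perm)])

    def test_coincident_centroids_rejected(self):
        atlas = RegionAtlas(
            region_ids=(1, 2),
            labels=("A", "B"),
            centroids=np.zeros((2, 3)),
            networks=("n", "n"),
        )
        with pytest.raises(ValidationError):
            euclidean_distances(atlas)


class TestEdgeCost:
    def test_direct_ratio(self):
        assert edge_cost(10.0, 0.5) == pytest.approx(20.0)

    def test_absent_edge_is_infinite(self):
        assert edge_cost(10.0, 0.0) == math.inf

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            edge_cost(0.0, 0.5)

    @given(
        d=st.floats(0.1, 1000),
        w1=st.floats(0.01, 1.0),
        w2=st.floats(0.01, 1.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_cost_decreasing_in_strength(self, d, w1, w2):
        lo, hi = sorted((w1, w2))
        if lo < hi:
            assert edge_cost(d, hi) < edge_cost(d, lo)


class TestFindEfficientPathway:
    def test_line_fixture_chain_beats_direct(self, line_dist, line_sc):
        route = find_efficient_pathway(line_dist, line_sc, 0, 3)
        assert route.nodes == (0, 1, 2, 3)
        assert route.n_steps == 3
        assert route.total_cost == pytest.approx(60.0, abs=1e-12)
        assert edge_cost(30.0, 0.1) == pytest.approx(300.0)

    def test_stronger_multistep_chain_preferred_over_direct(self):
        """A 4-step chain of strong edges wins against a similar-length weak direct link."""
        # nodes 0..4 roughly collinear; chain SC 0.9, direct 0-4 SC 0.2
        pts = np.array([[0, 0, 0], [10, 2, 0], [20, 0, 0], [30, 2, 0], [40, 0, 0.0]])
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        sc = np.zeros((5, 5))
        for i in range(4):
            sc[i, i + 1] = sc[i + 1, i] = 0.9
        sc[0, 4] = sc[4, 0] = 0.2
        route = find_efficient_pathway(d, sc, 0, 4, max_steps=4)
        assert route.nodes == (0, 1, 2, 3, 4)
        assert route.n_steps == 4

    def test_two_node_unique_path(self):
        d = np.array([[0.0, 7.0], [7.0, 0.0]])
        sc = np.array([[0.0, 0.5], [0.5, 0.0]])
        route = find_efficient_pathway(d, sc, 0, 1)
        assert route.nodes == (0, 1)
        assert route.n_steps == 1

    def test_reverse_route_same_cost(self, line_dist, line_sc):
        fwd = find_efficient_pathway(line_dist, line_sc, 0, 3)
        rev = find_efficient_pathway(line_dist, line_sc, 3, 0)
        assert rev.nodes == tuple(reversed(fwd.nodes))
        assert rev.total_cost == pytest.approx(fwd.total_cost, abs=1e-12)

    def test_hop_limit_forces_suboptimal_path(self):
        """When the unconstrained optimum needs 5 edges, the best <=4-edge route wins."""
        # chain 0-1-2-3-4-5 of very strong short edges; direct 0-5 weak edge
        pts = np.array([[i * 10.0, 0, 0] for i in range(6)])
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        sc = np.zeros((6, 6))
        for i in range(5):
            sc[i, i + 1] = sc[i + 1, i] = 0.9
        sc[0, 5] = sc[5, 0] = 0.3
        unconstrained = find_efficient_pathway(d, sc, 0, 5, max_steps=5)
        assert unconstrained.n_steps == 5  # 5 x 10/0.9 = 55.6 < 50/0.3 = 166.7
        limited = find_efficient_pathway(d, sc, 0, 5, max_steps=4)
        assert limited.n_steps <= 4
        oracle = brute_force_pathway(d, sc, 0, 5, max_steps=4)
        assert limited.nodes == oracle.nodes
        assert limited.total_cost == pytest.approx(oracle.total_cost, abs=1e-9)

    def test_absent_route_returns_none(self):
        d = np.array([[0.0, 5, 5], [5, 0, 5], [5, 5, 0.0]])
        sc = np.zeros((3, 3))
        sc[0, 1] = sc[1, 0] = 0.5  # node 2 isolated
        assert find_efficient_pathway(d, sc, 0, 2) is None
        assert brute_force_pathway(d, sc, 0, 2) is None

    def test_direct_edge_bound(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            d, sc = make_random_problem(rng, 8, 0.5)
            for i in range(8):
                for j in range(i + 1, 8):
                    if sc[i, j] > 0:
                        route = find_efficient_pathway(d, sc, i, j)
                        assert route is not None
                        assert route.total_cost <= d[i, j] / sc[i, j] + 1e-9

    @pytest.mark.parametrize("max_steps", [1, 2, 3, 4])
    def test_oracle_equivalence_random_graphs(self, max_steps):
        """Layered search matches exhaustive enumeration exactly (cost + tie-break)."""
        rng = np.random.default_rng(100 + max_steps)
        for _ in range(30):
            n = int(rng.integers(5, 11))
            d, sc = make_random_problem(rng, n, 0.4)
            for s in range(n):
                for t in range(s + 1, n):
                    fast = find_efficient_pathway(d, sc, s, t, max_steps)
                    slow = brute_force_pathway(d, sc, s, t, max_steps)
                    if slow is None:
                        assert fast is None
                    else:
                        assert fast.nodes == slow.nodes
                        assert fast.total_cost == pytest.approx(slow.total_cost, abs=1e-9)


class TestRouteAllPairs:
    def _subject(self, atlas, sc, fc_vals):
        fc = ConnMatrix(values=fc_vals, kind="FC", labels=atlas.labels)
        return SubjectConnectome(subject_id="s1", sc=sc, fc=fc)

    def test_all_zero_fc_routes_nothing(self, line_atlas, line_sc, line_dist):
        subj = self._subject(line_atlas, line_sc, np.zeros((4, 4)))
        table = route_all_pairs(subj, line_dist)
        assert table.n_routed == 0 and not table.unroutable

    def test_single_fc_pair_routes_chain(self, line_atlas, line_sc, line_dist):
        fc = np.zeros((4, 4))
        fc[0, 3] = fc[3, 0] = 0.4
        table = route_all_pairs(self._subject(line_atlas, line_sc, fc), line_dist)
        assert set(table.routes) == {(0, 3)}
        assert table.routes[(0, 3)].nodes == (0, 1, 2, 3)

    def test_disconnected_pair_unroutable(self, line_atlas, line_dist):
        sc_vals = np.zeros((4, 4))
        sc_vals[0, 1] = sc_vals[1, 0] = 0.5  # nodes 2, 3 isolated
        sc = ConnMatrix(values=sc_vals, kind="SC", labels=line_atlas.labels)
        fc = np.zeros((4, 4))
        fc[0, 2] = fc[2, 0] = 0.3
        table = route_all_pairs(self._subject(line_atlas, sc, fc), line_dist)
        assert table.unroutable == frozenset({(0, 2)})

    def test_masked_policy_requires_mask(self, line_atlas, line_sc, line_dist):
        subj = self._subject(line_atlas, line_sc, np.zeros((4, 4)))
        with pytest.raises(ValueError):
            route_all_pairs(subj, line_dist, fc_policy="masked")

    def test_routes_and_unroutable_partition_selection(self, small_dataset):
        _, atlas, subjects, _ = small_dataset
        D = euclidean_distances(atlas)
        table = route_all_pairs(subjects[0], D)
        n_selected = int((subjects[0].fc.values[np.triu_indices(atlas.n_regions, 1)] != 0).sum())
        assert table.n_routed + len(table.unroutable) == n_selected


class TestFcSignificanceMask:
    def test_strong_correlations_flagged_weak_not(self):
        n = 10
        fc = np.zeros((n, n))
        fc[0, 1] = fc[1, 0] = 0.9
        fc[2, 3] = fc[3, 2] = 0.02
        mask = fc_significance_mask(fc, n_timepoints=200)
        assert mask[0, 1] and not mask[2, 3]
        assert np.array_equal(mask, mask.T)
        assert not np.any(np.diagonal(mask))
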