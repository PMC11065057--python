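"""Weighted graph metrics: closed forms, oracles, invariances."""

import itertools

import networkx as nx
import numpy as np
import pytest

import usfc
from usfc.io import ValidationError
from usfc.metrics import (
    betweenness,
    compare_metrics,
    global_efficiency,
    local_efficiency,
    modularity_partition,
    modularity_q,
    nodal_efficiency,
    subject_metrics,
    to_length_graph,
)

from conftest import make_random_problem


def _complete(n, w):
    m = np.full((n, n), w, dtype=float)
    np.fill_diagonal(m, 0.0)
    return m


def _path_graph(n, w=1.0):
    m = np.zeros((n, n))
    for i in range(n - 1):
        m[i, i + 1] = m[i + 1, i] = w
    return m


class TestLengthGraph:
    def test_reciprocal_length(self):
        g = to_length_graph(_complete(3, 0.5))
        assert g[0][1]["length"] == pytest.approx(2.0)

    def test_zero_weight_no_edge(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 0.4
        g = to_length_graph(m)
        assert g.has_edge(0, 1) and not g.has_edge(1, 2)

    def test_scaling_homogeneity(self):
        m = _complete(4, 0.25)
        g1, g2 = to_length_graph(m), to_length_graph(2 * m)
        for u, v in g1.edges:
            assert g2[u][v]["length"] == pytest.approx(g1[u][v]["length"] / 2)

    def test_negative_weights_rejected(self):
        m = np.array([[0, -0.5], [-0.5, 0.0]])
        with pytest.raises(ValidationError):
            to_length_graph(m)


class TestEfficiency:
    def test_complete_k4_closed_form(self):
        # all lengths 1/0.5 = 2, so every pair has d = 2 and E_glob = 0.5
        assert global_efficiency(_complete(4, 0.5)) == pytest.approx(0.5)

    def test_isolated_node_zero(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 1.0
        ne = nodal_efficiency(m)
        le = local_efficiency(m)
        assert ne[2] == 0.0 and le[2] == 0.0

    def test_edge_removal_cannot_increase_efficiency(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            _, m = make_random_problem(rng, 7, 0.5)
            e = global_efficiency(m)
            edges = np.argwhere(np.triu(m, 1) > 0)
            if len(edges) == 0:
                continue
            i, j = edges[rng.integers(len(edges))]
            m2 = m.copy()
            m2[i, j] = m2[j, i] = 0.0
            assert global_efficiency(m2) <= e + 1e-12

    def test_local_efficiency_of_clique_member(self):
        # in K4(w=0.5), each node's neighbor subgraph is K3(w=0.5): E = 0.5
        le = local_efficiency(_complete(4, 0.5))
        np.testing.assert_allclose(le, 0.5)


class TestBetweenness:
    def test_path_middle_node(self):
        vec, mean = betweenness(_path_graph(3))
        assert vec[1] == pytest.approx(1.0)
        assert vec[0] == vec[2] == 0.0

    def test_complete_uniform_all_zero(self):
        vec, _ = betweenness(_complete(5, 0.7))
        np.testing.assert_allclose(vec, 0.0)

    def test_star_center(self):
        m = np.zeros((6, 6))
        for leaf in range(1, 6):
            m[0, leaf] = m[leaf, 0] = 1.0
        vec, _ = betweenness(m)
        assert vec[0] == pytest.approx(1.0)
        np.testing.assert_allclose(vec[1:], 0.0)

    def test_against_exhaustive_oracle(self):
        """Fractional shortest-path counting matches brute-force enumeration."""
        rng = np.random.default_rng(17)
        for _ in range(8):
            _, m = make_random_problem(rng, 7, 0.5)
            vec, _ = betweenness(m, normalized=True)
            np.testing.assert_allclose(vec, _betweenness_oracle(m), atol=1e-9)


def _betweenness_oracle(m: np.ndarray) -> np.ndarray:
    """Enumerate all simple paths per pair; share multiplicity fractionally."""
    n = m.shape[0]
    acc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        best, paths = np.inf, []
        stack = [((s,), 0.0)]
        while stack:
            path, cost = stack.pop()
            u = path[-1]
            if u == t:
                if cost < best - 1e-12:
                    best, paths = cost, [path]
                elif abs(cost - best) <= 1e-12:
                    paths.append(path)
                continue
            for v in range(n):
                if m[u, v] > 0 and v not in path:
                    stack.append((path + (v,), cost + 1.0 / m[u, v]))
        for path in paths:
            for v in path[1:-1]:
                acc[v] += 1.0 / len(paths)
    return acc / ((n - 1) * (n - 2) / 2)


class TestModularity:
    def _two_triangles(self):
        m = np.zeros((6, 6))
        for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            m[a, b] = m[b, a] = 1.0
        return m

    def test_two_disconnected_triangles(self):
        partition, q, contrib = modularity_partition(self._two_triangles())
        assert q == pytest.approx(0.5)
        assert len(set(partition[:3])) == 1 and len(set(partition[3:])) == 1
        assert partition[0] != partition[3]
        assert contrib.sum() == pytest.approx(q)

    def test_single_community_q_zero_on_complete_graph(self):
        m = _complete(5, 1.0)
        assert modularity_q(m, np.zeros(5, dtype=int)) == pytest.approx(0.0)

    def test_contributions_sum_to_q_random(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            _, m = make_random_problem(rng, 8, 0.5)
            if not np.any(m > 0):
                continue
            _, q, contrib = modularity_partition(m)
            assert contrib.sum() == pytest.approx(q, abs=1e-12)

    def test_q_matches_networkx(self):
        rng = np.random.default_rng(31)
        for _ in range(5):
            _, m = make_random_problem(rng, 9, 0.5)
            if not np.any(m > 0):
                continue
            partition, q, _ = modularity_partition(m)
            g = to_length_graph(m)
            comms = [set(np.flatnonzero(partition == c)) for c in np.unique(partition)]
            q_nx = nx.algorithms.community.modularity(g, comms, weight="weight")
            assert q == pytest.approx(q_nx, abs=1e-12)

    def test_greedy_q_at_least_trivial_partition(self):
        rng = np.random.default_rng(37)
        for _ in range(10):
            _, m = make_random_problem(rng, 8, 0.4)
            if not np.any(m > 0):
                continue
            _, q, _ = modularity_partition(m)
            assert q >= -1e-12  # trivial single-community partition has Q = 0

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ValidationError):
            modularity_partition(np.zeros((4, 4)))


class TestPermutationEquivariance:
    def test_metrics_follow_node_relabeling(self):
        rng = np.random.default_rng(41)
        _, m = make_random_problem(rng, 8, 0.6)
        perm = rng.permutation(8)
        mp = m[np.ix_(perm, perm)]
        np.testing.assert_allclose(
            nodal_efficiency(mp), nodal_efficiency(m)[perm], atol=1e-12
        )
        np.testing.assert_allclose(
            betweenness(mp)[0], betweenness(m)[0][perm], atol=1e-12
        )
        assert global_efficiency(mp) == pytest.approx(global_efficiency(m))


class TestCompareMetrics:
    def test_identical_matrices_no_significance(self, small_dataset):
        _, atlas, subjects, _ = small_dataset
        D = usfc.euclidean_distances(atlas)
        tables = [usfc.route_all_pairs(s, D) for s in subjects]
        usfc_list = [usfc.accumulate_usfc(t, s.fc) for t, s in zip(tables, subjects)]
        # compare USFC against itself by substituting SC := USFC and FC := USFC
        from usfc.io import ConnMatrix
        from usfc.routing import SubjectConnectome

        clones = [
            SubjectConnectome(
                subject_id=s.subject_id,
                sc=ConnMatrix(values=u.values, kind="SC", labels=atlas.labels),
                fc=ConnMatrix(values=np.clip(u.values / max(u.values.max(), 1), -1, 1),
                              kind="FC", labels=atlas.labels),
            )
            for s, u in zip(subjects, usfc_list)
        ]
        comp = compare_metrics(clones, usfc_list, normalize="max")
        for metric, (t, p) in comp.global_tests[("USFC", "SC")].items():
            assert t == 0.0 and p == 1.0

    def test_max_normalization_scale_invariant(self):
        rng = np.random.default_rng(3)
        _, m = make_random_problem(rng, 8, 0.6)
        r1 = subject_metrics(m / m.max())
        r2 = subject_metrics((3.7 * m) / (3.7 * m).max())
        assert r1["global_efficiency"] == pytest.approx(r2["global_efficiency"])
        assert r1["modularity_Q"] == pytest.approx(r2["modularity_Q"])

    def test_cohort_smoke_all_types_populated(self, small_dataset):
        _, atlas, subjects, _ = small_dataset
        D = usfc.euclidean_distances(atlas)
        tables = [usfc.route_all_pairs(s, D) for s in subjects]
        usfc_list = [usfc.accumulate_usfc(t, s.fc) for t, s in zip(tables, subjects)]
        comp = compare_metrics(subjects, usfc_list)
        for ctype in ("SC", "FC", "USFC"):
            eff = comp.global_values[ctype]["global_efficiency"]
            assert len(eff) == len(subjects)
            assert np.all(eff >= 0)
            q = comp.global_values[ctype]["modularity_Q"]
            assert np.all(q >= -0.5) and np.all(q <= 1.0)
            bet = comp.nodal_values[ctype]["betweenness"]
            assert np.all(bet >= 0) and np.all(bet <= 1)
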