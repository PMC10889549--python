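"""Graph statistics against hand-enumerated and brute-force oracles."""

from itertools import combinations

import numpy as np
import pytest

import brute
from skillnet import (
    RosterMismatchError,
    SimilarityNetwork,
    UndefinedMetricError,
    compare_sessions,
    density,
    global_clustering,
    jaccard_similarity,
    modularity,
    modularity_q,
    network_metrics,
    round_half_up,
    subnetwork_density,
)


def net_of(nodes, edges):
    return SimilarityNetwork(participants=list(nodes), edges=set(edges))


def complete(nodes):
    return net_of(nodes, combinations(nodes, 2))


P18 = [f"P{i:02d}" for i in range(1, 19)]


class TestDensity:
    def test_reported_eighteen_node_cell(self):
        # 46 edges on 18 nodes: 92/306 = 0.3007 -> 0.30 at two decimals
        edges = list(combinations(P18, 2))[:46]
        assert round_half_up(density(net_of(P18, edges)), 2) == 0.30

    def test_complete_graph(self):
        assert density(complete("abcd")) == 1.0

    def test_empty_graph(self):
        assert density(net_of(P18, [])) == 0.0

    def test_too_few_nodes(self):
        with pytest.raises(UndefinedMetricError):
            density(net_of(["a"], []))


class TestJaccard:
    def test_identical_nonempty(self):
        g = net_of("abc", [("a", "b")])
        assert jaccard_similarity(g, g) == 1.0

    def test_disjoint_nonempty(self):
        g1 = net_of("abcd", [("a", "b")])
        g2 = net_of("abcd", [("c", "d")])
        assert jaccard_similarity(g1, g2) == 0.0

    def test_enumerated_overlap(self):
        g1 = net_of("abcde", [("a", "b"), ("b", "c"), ("c", "d")])
        g2 = net_of("abcde", [("a", "b"), ("c", "d"), ("d", "e")])
        assert jaccard_similarity(g1, g2) == pytest.approx(0.5)

    def test_both_empty_convention(self):
        g1, g2 = net_of("abc", []), net_of("abc", [])
        assert jaccard_similarity(g1, g2) == 1.0

    def test_symmetry(self):
        g1 = net_of("abcd", [("a", "b"), ("b", "c")])
        g2 = net_of("abcd", [("a", "b"), ("c", "d")])
        assert jaccard_similarity(g1, g2) == jaccard_similarity(g2, g1)

    def test_roster_mismatch(self):
        with pytest.raises(RosterMismatchError):
            jaccard_similarity(net_of("abc", []), net_of("abd", []))


class TestClustering:
    def test_triangle(self):
        assert global_clustering(complete("abc")) == pytest.approx(1.0)

    def test_star_has_no_triangles(self):
        star = net_of("abcde", [("a", x) for x in "bcde"])
        assert global_clustering(star) == 0.0

    def test_path_with_chord(self):
        # a-b-c-d path plus a-c: locals are a:1, b:1, c:1/3, d:0
        g = net_of("abcd", [("a", "b"), ("b", "c"), ("c", "d"), ("a", "c")])
        assert round(global_clustering(g), 4) == 0.5833

    def test_transitivity_variant_differs(self):
        g = net_of("abcd", [("a", "b"), ("b", "c"), ("c", "d"), ("a", "c")])
        # 3 * 1 triangle / 5 connected triples
        assert global_clustering(g, variant="transitivity") == pytest.approx(3 / 5)

    def test_too_few_nodes(self):
        with pytest.raises(UndefinedMetricError):
            global_clustering(net_of("ab", [("a", "b")]))


class TestModularity:
    def test_single_community_q_is_zero(self):
        g = complete("abcd")
        q = modularity_q(g, {n: 0 for n in "abcd"})
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_two_disjoint_triangles(self):
        g = net_of(
            "abcdef",
            [("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f")],
        )
        partition, q = modularity(g)
        assert {frozenset(k for k, v in partition.items() if v == c) for c in set(partition.values())} == {
            frozenset("abc"),
            frozenset("def"),
        }
        assert q == pytest.approx(0.5)

    def test_q_matches_bruteforce_on_random_graph(self):
        rng = np.random.default_rng(42)
        edges = [e for e in combinations(P18, 2) if rng.random() < 0.25]
        g = net_of(P18, edges)
        partition, q = modularity(g)
        assert q == pytest.approx(brute.modularity_bf(P18, g.edges, partition), abs=1e-12)

    def test_deterministic_partition(self):
        rng = np.random.default_rng(3)
        edges = [e for e in combinations(P18, 2) if rng.random() < 0.3]
        assert modularity(net_of(P18, edges)) == modularity(net_of(P18, edges))

    def test_edgeless_graph_undefined(self):
        with pytest.raises(UndefinedMetricError):
            modularity(net_of("abc", []))


class TestSubnetworkDensity:
    def test_two_triangles(self):
        g = net_of(
            "abcdef",
            [("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f")],
        )
        out = subnetwork_density(g)
        assert [c["density"] for c in out.values()] == [1.0, 1.0]

    def test_k4_plus_isolates(self):
        nodes = P18
        edges = list(combinations(nodes[:4], 2))
        out = subnetwork_density(net_of(nodes, edges))
        densities = [c["density"] for c in out.values()]
        assert densities.count(1.0) == 1
        assert densities.count(None) == 14


class TestCompareSessions:
    def test_identical_networks(self):
        g = net_of("abc", [("a", "b")])
        comps = compare_sessions({1: g, 2: g, 3: g})
        assert [c.jaccard for c in comps] == [1.0, 1.0, 1.0]
        assert [c.pair for c in comps] == [(1, 2), (1, 3), (2, 3)]

    def test_hand_enumerated_jaccards(self):
        nets = {
            1: net_of("abcd", [("a", "b"), ("b", "c")]),
            2: net_of("abcd", [("a", "b"), ("c", "d")]),
            3: net_of("abcd", [("c", "d")]),
        }
        by_pair = {c.pair: c.jaccard for c in compare_sessions(nets)}
        assert by_pair[(1, 2)] == pytest.approx(1 / 3)
        assert by_pair[(1, 3)] == pytest.approx(0.0)
        assert by_pair[(2, 3)] == pytest.approx(1 / 2)

    def test_percent_difference_scale(self):
        nets = {
            1: net_of("abcd", [("a", "b"), ("b", "c"), ("c", "d")]),
            2: net_of("abcd", [("a", "b")]),
        }
        (comp,) = compare_sessions(nets)
        assert comp.percent_difference == pytest.approx((1 - 1 / 3) * 100)


class TestBruteForceEquivalence:
    """Exhaustive cross-check on every labelled graph with up to 5 nodes
    (the 6-node enumeration lives in the acceptance suite)."""

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_density_clustering_q_match(self, n):
        nodes = [chr(ord("a") + i) for i in range(n)]
        prev_edges = None
        for edges in brute.all_graphs(nodes):
            net = net_of(nodes, edges)
            assert density(net) == pytest.approx(
                brute.density_bf(nodes, edges), abs=1e-12
            )
            if n >= 3:
                assert global_clustering(net) == pytest.approx(
                    brute.avg_clustering_bf(nodes, edges), abs=1e-12
                )
            if edges:
                partition, q = modularity(net)
                assert q == pytest.approx(
                    brute.modularity_bf(nodes, edges, partition), abs=1e-12
                )
            if prev_edges is not None:
                assert jaccard_similarity(
                    net, net_of(nodes, prev_edges)
                ) == pytest.approx(brute.jaccard_bf(edges, prev_edges), abs=1e-12)
            prev_edges = edges


class TestNetworkMetricsBundle:
    def test_degenerate_networks_flow_through(self):
        m = network_metrics(net_of("abc", []))
        assert m.density == 0.0
        assert m.modularity_Q is None and m.partition is None

    def test_rounding_half_up(self):
        assert round_half_up(0.305, 2) == 0.31
        assert round_half_up(0.264, 2) == 0.26
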