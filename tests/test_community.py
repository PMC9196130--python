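import itertools

import networkx as nx
import numpy as np
import pytest

from danrlca import (
    AttributedGraph,
    CommunityAssignment,
    community_size_report,
    load_assignment,
    lpa,
    modularity,
    multilevel,
    toy_fixture,
)
from danrlca.graph_io import GraphFormatError

from conftest import brute_force_modularity


def complete_graph(n):
    return AttributedGraph.from_edges(n, itertools.combinations(range(n), 2))


class TestAssignment:
    def test_one_hot_rows_sum_to_one(self):
        P = CommunityAssignment.from_labels([3, 3, 7, 3])
        assert P.l == 2
        assert np.array_equal(P.C.sum(axis=1), np.ones(4))
        assert np.array_equal(P.membership, [0, 0, 1, 0])

    def test_rejects_non_contiguous(self):
        with pytest.raises(ValueError, match="contiguous"):
            CommunityAssignment(membership=np.array([0, 2]), l=3)


class TestLPA:
    def test_disjoint_triangles_two_communities(self, two_triangles):
        P = lpa(two_triangles, seed=0)
        assert P.l == 2
        assert len(set(P.membership[:3])) == 1
        assert len(set(P.membership[3:])) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_complete_graph_collapses_to_one(self, seed):
        assert lpa(complete_graph(5), seed=seed).l == 1

    def test_isolated_node_keeps_own_label(self, triangle_plus_isolate):
        P = lpa(triangle_plus_isolate, seed=0)
        assert P.l == 2
        assert P.membership[3] not in P.membership[:3]

    def test_components_never_share_labels(self):
        # two cliques of different sizes, disconnected
        edges = list(itertools.combinations(range(4), 2)) + [
            (i, j) for i, j in itertools.combinations(range(4, 10), 2)
        ]
        G = AttributedGraph.from_edges(10, edges)
        for seed in range(5):
            P = lpa(G, seed=seed)
            assert set(P.membership[:4]).isdisjoint(set(P.membership[4:]))

    def test_reproducible_with_seed(self, two_triangles):
        a = lpa(two_triangles, seed=42).membership
        b = lpa(two_triangles, seed=42).membership
        assert np.array_equal(a, b)

    def test_max_iter_validation(self, two_triangles):
        with pytest.raises(ValueError):
            lpa(two_triangles, seed=0, max_iter=0)


class TestModularity:
    def test_two_triangles_partition_is_half(self, two_triangles):
        P = CommunityAssignment.from_labels([0, 0, 0, 1, 1, 1])
        assert modularity(two_triangles, P) == pytest.approx(0.5)

    def test_single_community_is_zero(self, cycle6):
        P = CommunityAssignment.from_labels([0] * 6)
        assert modularity(cycle6, P) == pytest.approx(0.0, abs=1e-12)

    def test_four_cycle_adjacent_pairs_zero(self):
        G = AttributedGraph.from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
        P = CommunityAssignment.from_labels([0, 0, 1, 1])
        assert modularity(G, P) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_agrees_with_brute_force_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(12, 0.3, seed=seed)
        if g.number_of_edges() == 0:
            pytest.skip("edgeless draw")
        G = AttributedGraph.from_edges(12, g.edges())
        member = rng.integers(0, 3, size=12)
        P = CommunityAssignment.from_labels(member)
        assert modularity(G, P) == pytest.approx(
            brute_force_modularity(G, P.membership), abs=1e-10
        )

    def test_edgeless_errors(self):
        G = AttributedGraph.from_edges(3, [])
        P = CommunityAssignment.from_labels([0, 0, 0])
        with pytest.raises(ValueError):
            modularity(G, P)


class TestMultilevel:
    def test_two_triangles(self, two_triangles):
        P = multilevel(two_triangles, seed=0)
        assert P.l == 2
        assert modularity(two_triangles, P) == pytest.approx(0.5)

    def test_single_triangle_one_community(self):
        G = toy_fixture("two_triangles")
        tri = AttributedGraph.from_edges(3, [(0, 1), (1, 2), (0, 2)])
        assert multilevel(tri, seed=0).l == 1

    def test_barbell_splits_at_bridge(self):
        G = toy_fixture("barbell")
        P = multilevel(G, seed=0)
        assert P.l == 2
        assert len(set(P.membership[:4])) == 1
        assert len(set(P.membership[4:])) == 1

    @pytest.mark.parametrize("seed", range(3))
    def test_beats_singleton_partition(self, seed):
        g = nx.gnp_random_graph(20, 0.2, seed=seed + 10)
        G = AttributedGraph.from_edges(20, g.edges())
        P = multilevel(G, seed=seed)
        q_single = brute_force_modularity(G, np.arange(20))
        assert modularity(G, P) >= q_single

    def test_matches_networkx_louvain_quality(self):
        g = nx.planted_partition_graph(3, 12, 0.8, 0.05, seed=7)
        G = AttributedGraph.from_edges(36, g.edges())
        ours = modularity(G, multilevel(G, seed=0))
        theirs = nx.community.modularity(g, nx.community.louvain_communities(g, seed=0))
        assert ours == pytest.approx(theirs, abs=0.05)

    def test_reproducible_with_seed(self):
        g = nx.gnp_random_graph(25, 0.15, seed=3)
        G = AttributedGraph.from_edges(25, g.edges())
        assert np.array_equal(multilevel(G, seed=9).membership, multilevel(G, seed=9).membership)

    def test_edgeless_errors(self):
        with pytest.raises(ValueError):
            multilevel(AttributedGraph.from_edges(2, []), seed=0)


class TestLoadAssignment:
    def test_tokens_compacted_by_first_appearance(self, tmp_path):
        G = AttributedGraph.from_edges(3, [(0, 1), (1, 2)])
        p = tmp_path / "comm"
        p.write_text("0 A\n1 A\n2 B\n")
        P = load_assignment(p, G)
        assert np.array_equal(P.membership, [0, 0, 1])
        assert P.l == 2

    def test_missing_node_errors(self, tmp_path):
        G = AttributedGraph.from_edges(3, [(0, 1), (1, 2)])
        p = tmp_path / "comm"
        p.write_text("0 A\n1 A\n")
        with pytest.raises(GraphFormatError, match="missing"):
            load_assignment(p, G)

    def test_overlap_errors(self, tmp_path):
        G = AttributedGraph.from_edges(2, [(0, 1)])
        p = tmp_path / "comm"
        p.write_text("0 x\n0 y\n1 x\n")
        with pytest.raises(GraphFormatError, match="overlap"):
            load_assignment(p, G)


class TestSizeReport:
    @pytest.mark.parametrize(
        "member, l, fraction",
        [
            ([0, 0, 0, 1], 2, 0.75),
            ([0, 0, 0, 0], 1, 1.0),
            (list(range(10)), 10, 0.1),
        ],
    )
    def test_report(self, member, l, fraction):
        rep = community_size_report(CommunityAssignment.from_labels(member))
        assert rep["l"] == l
        assert sum(rep["sizes"]) == len(member)
        assert rep["largest_fraction"] == pytest.approx(fraction)
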