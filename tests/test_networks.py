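import numpy as np
import pytest

from dielnet.networks import (
    STANDARD_TAGS,
    CoexpressionNetwork,
    build_standard_networks,
    build_topk_network,
    intersect_networks,
    largest_component,
    mutual_information,
    network_summary,
    score_pairs,
)
from oracles import mutual_information_brute


class TestMutualInformation:
    def test_identical_binary_one_bit(self):
        assert mutual_information([0, 0, 1, 1], [0, 0, 1, 1], bins=2) == pytest.approx(1.0)

    def test_independent_zero_bits(self):
        assert mutual_information([0, 0, 1, 1], [0, 1, 0, 1], bins=2) == pytest.approx(0.0)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=12), rng.normal(size=12)
        assert mutual_information(x, y) == pytest.approx(mutual_information(y, x))

    def test_matches_definition_on_joint_table(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=24), rng.normal(size=24)
        bins = 3
        bx = np.minimum(((x - x.min()) / (x.max() - x.min()) * bins).astype(int), bins - 1)
        by = np.minimum(((y - y.min()) / (y.max() - y.min()) * bins).astype(int), bins - 1)
        joint = np.zeros((bins, bins))
        np.add.at(joint, (bx, by), 1)
        assert mutual_information(x, y, bins) == pytest.approx(
            mutual_information_brute(joint)
        )

    def test_bad_bins(self):
        with pytest.raises(ValueError):
            mutual_information([1, 2, 3], [1, 2, 3], bins=1)


class TestScorePairs:
    def _profiles(self):
        t = np.arange(12)
        base = np.cos(2 * np.pi * t / 12)
        return np.stack([base, base * 2 + 1, -base, np.arange(12, dtype=float)])

    def test_signed_and_absolute_behavior(self):
        prof = self._profiles()
        ids = ["a", "b", "c", "d"]
        signed = score_pairs(prof, ids, "signed_pearson")
        absolute = score_pairs(prof, ids, "abs_pearson")

        def get(sp, i, j):
            mask = (sp.i == i) & (sp.j == j)
            return float(sp.score[mask][0])

        assert get(signed, 0, 1) == pytest.approx(1.0)
        assert get(signed, 0, 2) == pytest.approx(-1.0)
        assert get(absolute, 0, 2) == pytest.approx(1.0)

    def test_no_self_pairs_and_pair_count(self):
        prof = self._profiles()
        sp = score_pairs(prof, list("abcd"), "signed_pearson")
        assert len(sp.score) == 6
        assert np.all(sp.i < sp.j)

    def test_zero_variance_gene_excluded(self, caplog):
        prof = np.vstack([self._profiles(), np.full(12, 3.0)])
        sp = score_pairs(prof, list("abcde"), "abs_pearson")
        assert 4 not in set(sp.i) | set(sp.j)

    def test_mi_scores_all_pairs(self):
        prof = self._profiles()
        sp = score_pairs(prof, list("abcd"), "mutual_information")
        assert len(sp.score) == 6
        assert np.all(sp.score >= -1e-12)


class TestTopK:
    def _scores(self, pair_scores, ids):
        n = len(ids)
        iu, ju = np.triu_indices(n, k=1)
        score = np.array([pair_scores[(ids[a], ids[b])] for a, b in zip(iu, ju)])
        from dielnet.networks import ScoredPairs

        return ScoredPairs(ids, iu, ju, score, "test")

    def test_top2_selection(self):
        ids = ["A", "B", "C", "D"]
        scores = self._scores(
            {("A", "B"): 0.9, ("A", "C"): 0.8, ("A", "D"): 0.7,
             ("B", "C"): 0.1, ("B", "D"): 0.2, ("C", "D"): 0.3},
            ids,
        )
        net = build_topk_network(scores, 0.5)  # K = 2
        assert set(map(frozenset, net.graph.edges())) == {
            frozenset({"A", "B"}), frozenset({"A", "C"})
        }

    def test_k_exceeding_pairs_gives_complete_graph(self):
        ids = ["A", "B", "C"]
        scores = self._scores(
            {("A", "B"): 0.5, ("A", "C"): 0.4, ("B", "C"): 0.3}, ids
        )
        net = build_topk_network(scores, 10)
        assert net.graph.number_of_edges() == 3

    def test_tie_at_threshold_broken_lexicographically(self):
        ids = ["A", "B", "C", "D"]
        scores = self._scores(
            {("A", "B"): 0.9, ("A", "C"): 0.5, ("A", "D"): 0.5,
             ("B", "C"): 0.5, ("B", "D"): 0.1, ("C", "D"): 0.1},
            ids,
        )
        net = build_topk_network(scores, 0.5)  # K = 2: tie among three 0.5 pairs
        assert net.graph.number_of_edges() == 2
        assert net.graph.has_edge("A", "B")
        assert net.graph.has_edge("A", "C")  # lexicographically first 0.5 pair

    def test_edge_monotonicity_in_k(self):
        rng = np.random.default_rng(0)
        prof = rng.normal(size=(30, 12))
        ids = [f"g{i:02d}" for i in range(30)]
        sp = score_pairs(prof, ids, "abs_pearson")
        small = build_topk_network(sp, 1.0)
        big = build_topk_network(sp, 3.0)
        assert set(map(frozenset, small.graph.edges())) <= set(
            map(frozenset, big.graph.edges())
        )


class TestIntersectAndComponents:
    def _net(self, edges, tag="t"):
        import networkx as nx

        g = nx.Graph()
        for u, v in edges:
            g.add_edge(u, v, weight=1.0)
        return CoexpressionNetwork(g, tag)

    def test_self_intersection_identity(self):
        a = self._net([("a", "b"), ("b", "c")])
        out = intersect_networks(a, a)
        assert set(map(frozenset, out.graph.edges())) == set(
            map(frozenset, a.graph.edges())
        )

    def test_disjoint_edge_sets_empty(self):
        a = self._net([("a", "b")])
        b = self._net([("c", "d")])
        assert intersect_networks(a, b).graph.number_of_edges() == 0

    def test_intersection_bounded(self):
        a = self._net([("a", "b"), ("b", "c"), ("c", "d")])
        b = self._net([("b", "c"), ("c", "d"), ("d", "e")])
        out = intersect_networks(a, b)
        assert out.graph.number_of_edges() <= min(3, 3)
        assert out.graph.number_of_edges() == 2

    def test_largest_component_selection(self):
        net = self._net(
            [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("x", "y"), ("y", "z")]
        )
        lcc = largest_component(net)
        assert lcc.nodes == {"a", "b", "c", "d", "e"}

    def test_component_tie_breaks_to_smallest_node(self):
        net = self._net([("b", "c"), ("c", "d"), ("x", "y"), ("y", "a")])
        lcc = largest_component(net)
        assert "a" in lcc.nodes

    def test_connected_unchanged(self):
        net = self._net([("a", "b"), ("b", "c")])
        assert largest_component(net).nodes == {"a", "b", "c"}

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            largest_component(self._net([]))

    def test_summary_counts(self):
        tri = self._net([("a", "b"), ("b", "c"), ("a", "c")])
        s = network_summary(tri)
        assert (s["n_nodes"], s["n_edges"], s["n_components"]) == (3, 3, 1)
        assert s["density"] == pytest.approx(1.0)
        two = self._net([("a", "b"), ("c", "d")])
        s2 = network_summary(two)
        assert (s2["n_nodes"], s2["n_edges"], s2["n_components"]) == (4, 2, 2)
        empty = network_summary(self._net([]))
        assert empty["n_nodes"] == 0 and empty["density"] == 0.0

    def test_edgelist_round_trip(self, tmp_path):
        net = self._net([("a", "b"), ("b", "c")])
        path = tmp_path / "net.tsv"
        net.write_edgelist(path)
        back = CoexpressionNetwork.read_edgelist(path, "t")
        assert set(map(frozenset, back.graph.edges())) == set(
            map(frozenset, net.graph.edges())
        )


class TestStandardNetworks:
    def test_five_networks_with_expected_tags(self):
        rng = np.random.default_rng(0)
        prof = rng.normal(size=(40, 12))
        ids = [f"g{i:02d}" for i in range(40)]
        nets = build_standard_networks(prof, ids)
        assert tuple(nets) == STANDARD_TAGS
        assert nets["SIGN_N"].graph.number_of_edges() == 40
        assert nets["ABS_N"].graph.number_of_edges() == 40
        # intersections are subsets of their parents' edge budgets
        assert nets["ABS_MI_10N"].graph.number_of_edges() <= 10 * 40


class TestPairwiseOverlaps:
    def test_overlap_table_symmetric_with_diagonal_edge_counts(self):
        rng = np.random.default_rng(3)
        prof = rng.normal(size=(30, 12))
        ids = [f"g{i:02d}" for i in range(30)]
        from dielnet.networks import pairwise_edge_overlaps

        nets = build_standard_networks(prof, ids)
        table = pairwise_edge_overlaps(nets)
        for tag, net in nets.items():
            assert table.loc[tag, tag] == net.graph.number_of_edges()
        assert (table.to_numpy() == table.to_numpy().T).all()
        # an intersection network's edges all appear in its parents' rankings
        assert table.loc["ABS_MI_10N", "ABS_MI_25N"] >= 0
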