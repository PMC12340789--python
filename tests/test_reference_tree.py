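"""Spanning reference tree: construction, positions, orientations, LCA."""

import random

import pytest

import treevar as tv
from treevar.errors import ConfigurationError, EmptyGraphError
from treevar.graph_core import FORWARD, REVERSE, BidirectedGraph
from treevar.reference_tree import SOURCE_A, TERMINUS_NODES, build_tree

from conftest import build_graph


class TestBuildTree:
    def test_fig1_non_tree_edges_are_the_three_variant_edges(self, fig1_analysis):
        _, expected, tree, _ = fig1_analysis
        non_tree = {
            tuple(sorted(e.node_ids)) for e in tree.graph_non_tree_edges()
        }
        assert non_tree == {("1", "4"), ("7", "8"), ("3", "9")}

    def test_reference_walk_edges_are_all_tree_edges(self, fig1_analysis):
        graph, _, tree, _ = fig1_analysis
        ref_walk = graph.reference_walks()[0]
        assert all(e in tree.tree_edges for e in ref_walk.edges())

    def test_tree_spans_every_node_with_a_chain_to_the_root(self, fig1_analysis):
        graph, _, tree, _ = fig1_analysis
        for n in graph.nodes:
            seen = set()
            while tree.parent[n] is not None:
                assert n not in seen
                seen.add(n)
                n = tree.parent[n][0]
            assert n == SOURCE_A

    def test_tree_edge_count_matches_spanning_invariant(self, fig1_analysis):
        graph, _, tree, _ = fig1_analysis
        # |V| graph nodes + 4 terminus nodes, one edge per non-root node
        assert len(tree.tree_edges) == len(graph.nodes) + 4 - 1

    def test_terminus_binodes_have_empty_sequences_and_anchor_walks(
        self, fig1_analysis
    ):
        graph, _, tree, _ = fig1_analysis
        assert tree.terminus_nodes == TERMINUS_NODES
        assert all(tree.oriented_sequence(t) == "" for t in TERMINUS_NODES)
        for walk in graph.walks:
            start, end = tree.terminus_edges_for_walk(walk)
            assert start in tree.wiring_edges and end in tree.wiring_edges

    def test_reference_only_graph_has_no_variant_candidates(self):
        g = build_graph({"1": "AC", "2": "GT"}, [("GRCh38", ["1", "2"])])
        tree = build_tree(g)
        assert tv.call_variants(g, tree) == []

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_non_tree_edge_count_oracle(self, seed):
        cfg = tv.SimulationConfig(seed=seed, reference_length=3000, n_snps=8,
                                  n_small_indels=2, n_large_deletions=1,
                                  n_inversions=1, n_nested_snp_insertions=1)
        g, _ = tv.simulate(cfg)
        tree = build_tree(g)
        assert len(tree.graph_non_tree_edges()) == \
            len(g.edges) - (len(g.nodes) - 1)

    def test_empty_graph_rejected(self):
        with pytest.raises(EmptyGraphError):
            build_tree(BidirectedGraph())

    def test_missing_reference_walk_rejected(self):
        g = build_graph({"1": "A", "2": "C"}, [("other", ["1", "2"])])
        with pytest.raises(ConfigurationError):
            build_tree(g)

    def test_cyclic_reference_walk_rejected(self):
        g = build_graph({"1": "A", "2": "C"}, [("GRCh38", ["1", "2", "1"])])
        with pytest.raises(ConfigurationError, match="revisits"):
            build_tree(g)

    def test_component_without_walks_is_anchored_with_position_minus_one(self):
        g = build_graph({"1": "A", "2": "C"}, [("GRCh38", ["1", "2"])])
        g.add_node("9", "TTTT")
        tree = build_tree(g)
        assert tree.position["9"] == -1
        assert tree.parent["9"] is not None  # anchored to the source binode


class TestPositionsAndOrientation:
    def test_reference_positions_are_cumulative_last_base_coordinates(
        self, fig1_analysis
    ):
        _, _, tree, _ = fig1_analysis
        # ref path 1(A) 2(CG) 3(T) 4(CT) 5(G) 8(AT) 11(GG)
        assert [tree.node_position(n) for n in tree.reference_path] == \
            [1, 3, 4, 6, 7, 9, 11]

    def test_positions_non_decreasing_along_reference(self, fig1_analysis):
        _, _, tree, _ = fig1_analysis
        pos = [tree.node_position(n) for n in tree.reference_path]
        assert pos == sorted(pos)

    def test_off_reference_node_inherits_branch_coordinate(self, fig1_analysis):
        _, _, tree, _ = fig1_analysis
        # 10 and 9 hang off node 2 (position 3); 6 and 7 off node 3 (position 4)
        assert tree.node_position("10") == tree.node_position("9") == 3
        assert tree.node_position("6") == tree.node_position("7") == 4

    def test_unknown_node_raises_key_error(self, fig1_analysis):
        _, _, tree, _ = fig1_analysis
        with pytest.raises(KeyError):
            tree.node_position("nope")
        with pytest.raises(KeyError):
            tree.orient("nope")

    def test_reference_path_nodes_are_forward(self, fig1_analysis):
        _, _, tree, _ = fig1_analysis
        assert all(tree.orient(n) == FORWARD for n in tree.reference_path)

    def test_side_flipping_edge_forces_reverse_orientation(self):
        # walk enters node 2 through its head: reverse-complement traversal
        g = build_graph(
            {"1": "AC", "2": "GT", "3": "AA"},
            [("GRCh38", ["1", "3"]), ("w", ["1", ("2", REVERSE), "3"])],
        )
        tree = build_tree(g)
        assert tree.orient("2") == REVERSE

    def test_simulated_inversion_interior_stays_forward_reference(self):
        # the inverted segment lies on the reference, so its tree
        # orientation is forward; only the flanking edges are inversions
        cfg = tv.SimulationConfig(seed=9, reference_length=1500, n_snps=0,
                                  n_small_indels=0, n_large_deletions=0,
                                  n_inversions=1, n_nested_snp_insertions=0)
        g, _ = tv.simulate(cfg)
        tree = build_tree(g)
        variants = tv.call_variants(g, tree)
        assert {v.vtype for v in variants} == {"inversion"}
        assert all(tree.orient(n) == FORWARD for n in tree.reference_path)


class TestLca:
    def brute_force_lca(self, tree, a, b):
        up = lambda n: set(tree.path_up(n, SOURCE_A))
        common = up(a) & up(b)
        return max(common, key=lambda n: tree.depth[n])

    def test_identity_and_root_cases(self, fig1_analysis):
        _, _, tree, _ = fig1_analysis
        assert tree.lca("5", "5") == "5"
        assert tree.lca(SOURCE_A, "5") == SOURCE_A

    def test_matches_brute_force_on_random_pairs(self, fig1_analysis):
        _, _, tree, _ = fig1_analysis
        rng = random.Random(0)
        nodes = list(tree.parent)
        for _ in range(200):
            a, b = rng.choice(nodes), rng.choice(nodes)
            assert tree.lca(a, b) == self.brute_force_lca(tree, a, b)

    def test_matches_brute_force_on_simulated_tree(self):
        cfg = tv.SimulationConfig(seed=4, reference_length=800, n_snps=4,
                                  n_small_indels=1, n_large_deletions=1,
                                  n_inversions=0, n_nested_snp_insertions=1)
        g, _ = tv.simulate(cfg)
        tree = build_tree(g)
        rng = random.Random(1)
        nodes = list(tree.parent)
        for _ in range(200):
            a, b = rng.choice(nodes), rng.choice(nodes)
            assert tree.lca(a, b) == self.brute_force_lca(tree, a, b)


class TestTieBreakInvariance:
    def test_variant_edge_count_is_invariant_to_tree_choice(self):
        cfg = tv.SimulationConfig(seed=17, reference_length=3000, n_snps=8,
                                  n_small_indels=2, n_large_deletions=1,
                                  n_inversions=1, n_nested_snp_insertions=0)
        g, _ = tv.simulate(cfg)
        counts = set()
        for r in range(5):
            tree = build_tree(g, tie_break_rng=random.Random(r))
            counts.add(len(tv.call_variants(g, tree)))
        assert len(counts) == 1


class TestTreeDump:
    def test_tsv_lists_every_node(self, fig1_analysis, tmp_path):
        graph, _, tree, _ = fig1_analysis
        p = tmp_path / "tree.tsv"
        tree.to_tsv(p)
        lines = p.read_text().splitlines()
        assert len(lines) == 1 + len(graph.nodes) + 4
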