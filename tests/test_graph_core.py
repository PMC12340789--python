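"""Bidirected graph model, GFA I/O, extraction and simplification."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import treevar as tv
from treevar.errors import (
    ConfigurationError,
    GfaParseError,
    ReferentialIntegrityError,
)
from treevar.graph_core import (
    FORWARD,
    REVERSE,
    BidirectedEdge,
    OrientedNode,
    read_gfa,
    write_gfa,
)

from conftest import build_graph


class TestEdgeCanonicalization:
    def test_link_and_its_reverse_complement_are_one_edge(self):
        assert BidirectedEdge.from_link("1", "+", "2", "+") == \
            BidirectedEdge.from_link("2", "-", "1", "-")
        assert BidirectedEdge.from_link("1", "+", "2", "-") == \
            BidirectedEdge.from_link("2", "+", "1", "-")

    def test_oriented_node_double_reverse_is_identity(self):
        x = OrientedNode("7", FORWARD)
        assert x.reverse().reverse() == x
        assert x.reverse().orientation == REVERSE

    @settings(deadline=None, derandomize=True)
    @given(
        a=st.text(alphabet="abc123", min_size=1, max_size=4),
        oa=st.sampled_from("+-"),
        b=st.text(alphabet="abc123", min_size=1, max_size=4),
        ob=st.sampled_from("+-"),
    )
    def test_any_link_equals_its_strand_flip(self, a, oa, b, ob):
        flip = {"+": "-", "-": "+"}
        e1 = BidirectedEdge.from_link(a, oa, b, ob)
        e2 = BidirectedEdge.from_link(b, flip[ob], a, flip[oa])
        assert e1 == e2 and hash(e1) == hash(e2)
        # the emitted L-line reading reparses to the same canonical edge
        assert BidirectedEdge.from_link(*e1.link_fields()) == e1


class TestReadGfa:
    def test_minimal_single_segment_file(self, tmp_path):
        p = tmp_path / "one.gfa"
        p.write_text("S\tn1\tACGT\n")
        g = read_gfa(p, reference_name="GRCh38")
        assert len(g.nodes) == 1 and not g.edges and not g.walks

    def test_fig1_gfa_has_eleven_nodes(self, fig1, tmp_path):
        graph, expected = fig1
        p = tmp_path / "fig1.gfa"
        write_gfa(graph, p)
        g = read_gfa(p, "GRCh38")
        assert len(g.nodes) == expected["n_nodes"] == 11

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.gfa"
        p.write_text("S\t1\tACGT\nL\t1\t+\n")
        with pytest.raises(GfaParseError, match="line 2"):
            read_gfa(p, "GRCh38")

    def test_link_to_unknown_segment_is_referential_error(self, tmp_path):
        p = tmp_path / "bad.gfa"
        p.write_text("S\t1\tACGT\nL\t1\t+\t9\t+\t0M\n")
        with pytest.raises(ReferentialIntegrityError, match="9"):
            read_gfa(p, "GRCh38")

    def test_missing_reference_sample_is_configuration_error(self, tmp_path):
        p = tmp_path / "bad.gfa"
        p.write_text("S\t1\tACGT\nW\tother\t0\tchr\t*\t*\t>1\n")
        with pytest.raises(ConfigurationError, match="GRCh38"):
            read_gfa(p, "GRCh38")

    def test_p_lines_become_unphased_walks(self, tmp_path):
        p = tmp_path / "p.gfa"
        p.write_text(
            "S\t1\tAC\nS\t2\tGT\nL\t1\t+\t2\t+\t0M\nP\tGRCh38\t1+,2+\t*\n"
        )
        g = read_gfa(p, "GRCh38")
        assert len(g.walks) == 1
        assert g.walks[0].hap_index == 0
        assert [s.orientation for s in g.walks[0].steps] == [FORWARD, FORWARD]

    def test_iupac_codes_map_to_n_with_warning(self, tmp_path):
        p = tmp_path / "iupac.gfa"
        p.write_text("S\t1\tACRY\n")
        with pytest.warns(UserWarning, match="non-ACGTN"):
            g = read_gfa(p, "GRCh38")
        assert g.nodes["1"] == "ACNN"


class TestRoundTrip:
    @pytest.mark.parametrize("seed", [0, 7, 13, 21, 42])
    def test_simulated_graph_round_trips_byte_identically(self, seed, tmp_path):
        cfg = tv.SimulationConfig(seed=seed, reference_length=2000, n_snps=5,
                                  n_small_indels=2, n_large_deletions=1,
                                  n_inversions=1, n_nested_snp_insertions=1)
        g, _ = tv.simulate(cfg)
        p1, p2 = tmp_path / "a.gfa", tmp_path / "b.gfa"
        write_gfa(g, p1)
        g2 = read_gfa(p1, cfg.reference_name)
        write_gfa(g2, p2)
        assert p1.read_text() == p2.read_text()
        assert g2.nodes == g.nodes and g2.edges == g.edges
        assert [(w.sample, w.hap_index, w.steps) for w in g2.walks] == \
            [(w.sample, w.hap_index, w.steps) for w in g.walks]

    def test_walkless_graph_writes_no_w_lines(self, tmp_path):
        g = tv.BidirectedGraph()
        g.add_node("1", "ACGT")
        p = tmp_path / "nw.gfa"
        write_gfa(g, p)
        assert not any(line.startswith("W") for line in p.read_text().splitlines())


class TestExtractComponent:
    def two_component_graph(self):
        g = build_graph(
            {"1": "A", "2": "C", "3": "G", "4": "T"},
            [("GRCh38", ["1", "2"]), ("other", ["3", "4"])],
        )
        return g

    def test_seed_in_first_component_returns_only_it(self):
        g = self.two_component_graph()
        sub = tv.extract_component(g, "1")
        assert set(sub.nodes) == {"1", "2"}
        assert all(set(e.node_ids) <= {"1", "2"} for e in sub.edges)

    def test_connected_graph_is_identity(self, fig1):
        graph, _ = fig1
        sub = tv.extract_component(graph, "5")
        assert sub.nodes == graph.nodes and sub.edges == graph.edges

    def test_components_partition_the_node_set(self):
        g = self.two_component_graph()
        comps = {frozenset(g.component_nodes(n)) for n in g.nodes}
        assert sum(len(c) for c in comps) == len(g.nodes)

    def test_walks_restricted_to_component(self):
        g = self.two_component_graph()
        sub = tv.extract_component(g, "3")
        assert [w.sample for w in sub.walks] == ["other"]

    def test_unknown_seed_raises_key_error(self, fig1):
        with pytest.raises(KeyError):
            tv.extract_component(fig1[0], "nope")


class TestSimplify:
    def test_prune_everything_leaves_single_reference_node(self, fig1_analysis):
        graph, expected, tree, variants = fig1_analysis
        s = tv.simplify(graph, variants, 10 ** 9)
        assert len(s.nodes) == 1 and len(s.edges) == 0
        (seq,) = s.nodes.values()
        assert seq == expected["reference_sequence"]

    def test_zero_threshold_preserves_variant_structure(self, fig1_analysis):
        graph, _, tree, variants = fig1_analysis
        s = tv.simplify(graph, variants, 0)
        # all variant edges survive: same cycle space, only contraction
        assert len(s.edges) - len(s.nodes) == len(graph.edges) - len(graph.nodes)
        assert s.total_sequence_length() == graph.total_sequence_length()

    def test_long_insertion_survives_where_snps_are_pruned(self):
        cfg = tv.SimulationConfig(seed=5, reference_length=6000, n_snps=50,
                                  n_small_indels=0, n_large_deletions=0,
                                  n_inversions=0, n_nested_snp_insertions=0,
                                  n_large_insertions=1, n_haplotypes=3)
        g, _ = tv.simulate(cfg)
        tree = tv.build_tree(g)
        variants = tv.call_variants(g, tree)
        s = tv.simplify(g, variants, 50)
        # one surviving bubble: two reference super-nodes plus the insertion
        assert len(s.nodes) == 3 and len(s.edges) == 3

    def test_reference_walk_survives_simplification(self, fig1_analysis):
        graph, _, tree, variants = fig1_analysis
        s = tv.simplify(graph, variants, 10 ** 9)
        ref = [w for w in s.walks if w.sample == "GRCh38"]
        assert ref and "".join(
            s.nodes[st.node_id] for st in ref[0].steps
        ) == tree.reference_sequence()

    def test_negative_threshold_rejected(self, fig1_analysis):
        graph, _, _, variants = fig1_analysis
        with pytest.raises(ValueError):
            tv.simplify(graph, variants, -1)
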