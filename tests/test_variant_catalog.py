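"""Variant edges: calling, typing, alleles, annotation, exclusions."""

import random
from types import SimpleNamespace

import pytest

import treevar as tv
from treevar.errors import NotApplicableError
from treevar.variant_catalog import (
    annotate_repeat,
    branch_point,
    call_variants,
    flag_nia,
)

from conftest import build_graph


def by_pair(variants):
    return {v.node_pair: v for v in variants}


class TestFig1Catalog:
    def test_three_variants_with_expected_types(self, fig1_analysis):
        _, expected, _, variants = fig1_analysis
        assert {v.node_pair: v.vtype for v in variants} == \
            expected["variant_edges"]

    def test_alleles_match_transcription(self, fig1_analysis):
        _, expected, _, variants = fig1_analysis
        for v in variants:
            assert (v.ref_seq, v.alt_seq) == expected["alleles"][v.node_pair]

    def test_branch_points(self, fig1_analysis):
        _, _, _, variants = fig1_analysis
        got = {v.node_pair: v.branch_point for v in variants}
        assert got == {("1", "4"): "1", ("9", "3"): "2", ("7", "8"): "3"}

    def test_deletion_has_empty_alt_and_branch_at_u(self, fig1_analysis):
        _, _, _, variants = fig1_analysis
        deletion = by_pair(variants)[("1", "4")]
        assert deletion.alt_seq == "" and deletion.branch_point == deletion.u

    def test_terminal_edges_of_fragmented_walks_are_excluded(self, fig1_analysis):
        # the fragmented haplotype contributes four terminal edges; none
        # may surface as variants
        _, _, tree, variants = fig1_analysis
        assert len(variants) == 3
        candidates = tree.variant_candidate_edges()
        assert len(candidates) > 3  # terminal edges existed and were dropped


class TestTyping:
    @pytest.mark.parametrize(
        "kwargs, expected_type",
        [
            (dict(n_snps=1), "SNP"),
            (dict(n_small_indels=0, n_large_deletions=1), "deletion"),
            (dict(n_large_insertions=1), "insertion"),
            (dict(n_tandem_duplications=1), "duplication"),
            (dict(n_inversions=1), "inversion"),
        ],
    )
    def test_single_planted_event_gets_its_type(self, kwargs, expected_type):
        base = dict(n_snps=0, n_small_indels=0, n_large_insertions=0,
                    n_large_deletions=0, n_inversions=0,
                    n_tandem_duplications=0, n_nested_snp_insertions=0,
                    reference_length=1500, n_haplotypes=3, seed=11)
        base.update(kwargs)
        g, truth = tv.simulate(tv.SimulationConfig(**base))
        tree = tv.build_tree(g)
        variants = call_variants(g, tree)
        assert {v.vtype for v in variants} == {expected_type}
        assert len(variants) == len(truth.entries)

    def test_size_class_threshold_at_50_combined_bp(self):
        def stub(vtype, ref_seq, alt_seq):
            return tv.VariantEdge(
                edge=None, u="u", v="v", u_exit_side="head",
                v_entry_side="tail", branch_point="u", ref_path=[],
                alt_path=[], ref_seq=ref_seq, alt_seq=alt_seq, vtype=vtype,
                pos_pair=(1, 2), non_reference=False,
            )
        assert stub("deletion", "A" * 30, "").size_class == "small"
        assert stub("deletion", "A" * 50, "").size_class == "large"
        assert stub("inversion", "", "").size_class == "large"

    def test_mnp_requires_equal_multibase_alleles(self):
        g = build_graph(
            {"1": "A", "2": "CT", "3": "G", "4": "GA"},
            [("GRCh38", ["1", "2", "3"]), ("w", ["1", "4", "3"])],
        )
        tree = tv.build_tree(g)
        (v,) = call_variants(g, tree)
        assert v.vtype == "MNP" and (v.ref_seq, v.alt_seq) == ("CT", "GA")

    def test_degenerate_identical_alleles_are_excluded(self):
        g = build_graph(
            {"1": "A", "2": "CT", "3": "G", "4": "CT"},
            [("GRCh38", ["1", "2", "3"]), ("w", ["1", "4", "3"])],
        )
        tree = tv.build_tree(g)
        assert call_variants(g, tree) == []

    def test_edge_traversed_both_ways_yields_one_variant_per_direction(self):
        g = build_graph(
            {"1": "A", "2": "C", "3": "T"},
            [("GRCh38", ["1", "2", "3"]),
             ("w1", ["1", "3"]),
             ("w2", [("3", "-"), ("1", "-")])],
        )
        tree = tv.build_tree(g)
        with pytest.warns(UserWarning, match="both directions"):
            variants = call_variants(g, tree)
        assert sorted(v.vtype for v in variants) == ["deletion", "duplication"]

    def test_non_reference_iff_target_off_the_reference_walk(self):
        cfg = tv.SimulationConfig(seed=2)
        g, _ = tv.simulate(cfg)
        tree = tv.build_tree(g)
        for v in call_variants(g, tree):
            assert v.non_reference == (not tree.on_reference(v.v))


class TestBranchPointAndAlleles:
    def test_duplication_branches_at_v_with_empty_ref(self):
        cfg = tv.SimulationConfig(seed=11, reference_length=1500, n_snps=0,
                                  n_small_indels=0, n_large_deletions=0,
                                  n_inversions=0, n_nested_snp_insertions=0,
                                  n_tandem_duplications=1, n_haplotypes=3)
        g, _ = tv.simulate(cfg)
        tree = tv.build_tree(g)
        (v,) = call_variants(g, tree)
        assert v.vtype == "duplication"
        assert v.branch_point == v.v and v.ref_seq == ""

    def test_branch_point_is_lca(self, fig1_analysis):
        _, _, tree, variants = fig1_analysis
        for v in variants:
            assert branch_point(tree, v.u, v.v) == tree.lca(v.u, v.v)

    def test_branch_point_rejects_opposite_orientations(self):
        g = build_graph(
            {"1": "AC", "2": "GT", "3": "AA"},
            [("GRCh38", ["1", "3"]), ("w", ["1", ("2", "-"), "3"])],
        )
        tree = tv.build_tree(g)
        with pytest.raises(NotApplicableError):
            branch_point(tree, "1", "2")

    def test_alleles_function_matches_catalog(self, fig1_analysis):
        _, _, tree, variants = fig1_analysis
        for v in variants:
            assert tv.alleles(tree, v.u, v.v) == (v.ref_seq, v.alt_seq)


class TestRepeatAnnotation:
    def insertion_fixture(self, upstream, allele, downstream):
        g = build_graph(
            {"1": upstream, "2": downstream, "3": allele},
            [("GRCh38", ["1", "2"]), ("w", ["1", "3", "2"])],
        )
        tree = tv.build_tree(g)
        (v,) = call_variants(g, tree)
        assert v.vtype == "insertion"
        return v, tree

    def test_tandem_insertion_with_matching_upstream_flank(self):
        v, tree = self.insertion_fixture("CCAT", "ATAT", "GGG")
        assert annotate_repeat(v, tree) == "AT"
        assert v.tr_motif == "AT"

    def test_insertion_without_matching_flank_has_no_motif(self):
        v, tree = self.insertion_fixture("CCC", "ATG", "CAA")
        assert annotate_repeat(v, tree) is None

    def test_downstream_flank_also_qualifies(self):
        v, tree = self.insertion_fixture("CCC", "TG", "TGAA")
        assert annotate_repeat(v, tree) == "TG"

    def test_matches_brute_force_period_scan(self):
        rng = random.Random(0)
        for _ in range(40):
            up = "".join(rng.choice("ACGT") for _ in range(6))
            down = "".join(rng.choice("ACGT") for _ in range(6))
            motif = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 3)))
            allele = motif * rng.randint(1, 3)
            v, tree = self.insertion_fixture(up, allele, down)

            def brute():
                n = len(allele)
                for p in range(1, n + 1):
                    s = allele[:p]
                    if n % p or s * (n // p) != allele:
                        continue
                    if up.endswith(s) or down.startswith(s):
                        return s
                return None

            assert annotate_repeat(v, tree) == brute()


class TestNearlyIdenticalAlleles:
    @pytest.mark.parametrize(
        "ref, alt, expected",
        [
            ("ACGTACGTACGT", "ACGTACGAACGT", True),   # 12 bp, one substitution
            ("ACGTACGTACGT", "ACGTACGACGT", True),    # 12 vs 11 bp, 1-bp deletion
            ("ACGTACGTA", "ACGTACGAA", False),        # 9 bp: below length gate
            ("ACGTACGTACGT", "ACGTAAAAACGT", False),  # three substitutions
        ],
    )
    def test_flagging_rule(self, ref, alt, expected):
        v = SimpleNamespace(ref_seq=ref, alt_seq=alt, nia=False)
        assert flag_nia([v]) == [expected]
        assert v.nia is expected
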