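"""Shared builders for hand-made bidirected graphs and walk enumeration."""

from __future__ import annotations

import pytest

from treevar.graph_core import (
    FORWARD,
    REVERSE,
    TAIL,
    BidirectedEdge,
    BidirectedGraph,
    OrientedNode,
    Walk,
    exit_side,
)
from treevar import build_tree, call_variants, fig1_fixture


def build_graph(seqs: dict, walks: list, reference: str = "GRCh38") -> BidirectedGraph:
    """Graph from {node: seq} and [(sample, [ids or (id, orient)])];
    edges are exactly the adjacencies the walks traverse."""
    g = BidirectedGraph(reference_name=reference)
    for nid, seq in seqs.items():
        g.add_node(nid, seq)
    for sample, ids in walks:
        steps = [
            OrientedNode(*i) if isinstance(i, tuple) else OrientedNode(i, FORWARD)
            for i in ids
        ]
        for a, b in zip(steps, steps[1:]):
            g.edges.add(BidirectedEdge.from_steps(a, b))
        g.add_walk(Walk(sample, 0, steps))
    return g


def enumerate_walks(g: BidirectedGraph, max_len: int, max_edge_visits: int = 2):
    """All walks of length <= max_len using each edge <= max_edge_visits."""
    side_index = g.side_index()
    out = []

    def extend(steps, used):
        out.append(list(steps))
        if len(steps) >= max_len:
            return
        last = steps[-1]
        end = (last.node_id, exit_side(last.orientation))
        for e in side_index.get(end, []):
            try:
                other, oside = e.other_end(end)
            except KeyError:
                continue
            if used.get(e, 0) >= max_edge_visits:
                continue
            used[e] = used.get(e, 0) + 1
            steps.append(OrientedNode(other, FORWARD if oside == TAIL else REVERSE))
            extend(steps, used)
            steps.pop()
            used[e] -= 1

    for nid in g.nodes:
        for o in (FORWARD, REVERSE):
            extend([OrientedNode(nid, o)], {})
    return out


# ---------------------------------------------------------------------
# toy worked-example fixture, analysed once per session
# ---------------------------------------------------------------------

@pytest.fixture(scope="session")
def fig1():
    graph, expected = fig1_fixture()
    return graph, expected


@pytest.fixture(scope="session")
def fig1_analysis(fig1):
    graph, expected = fig1
    tree = build_tree(graph)
    variants = call_variants(graph, tree)
    return graph, expected, tree, variants


# ---------------------------------------------------------------------
# triallelic taxonomy fixtures (two-variant superbubbles)
# ---------------------------------------------------------------------

def properly_triallelic_graph():
    """Three single-node alleles between shared degree-3 junctions."""
    return build_graph(
        {"1": "A", "2": "T", "3": "G", "4": "C", "5": "A"},
        [("GRCh38", ["1", "2", "3"]),
         ("w1", ["1", "4", "3"]),
         ("w2", ["1", "5", "3"])],
    )


def overlapping_graph():
    """A SNP and a longer replacement sharing the bubble entry only."""
    return build_graph(
        {"1": "A", "2": "C", "3": "T", "4": "G", "5": "G", "6": "GG"},
        [("GRCh38", ["1", "2", "3", "4"]),
         ("w1", ["1", "5", "3", "4"]),
         ("w2", ["1", "6", "4"])],
    )


def nested_graph():
    """A SNP nested inside an insertion (entry and exit tree-adjacent)."""
    return build_graph(
        {"1": "A", "2": "G", "3": "AC", "4": "T", "5": "G", "6": "CA"},
        [("GRCh38", ["1", "2"]),
         ("w1", ["1", "3", "4", "6", "2"]),
         ("w2", ["1", "3", "5", "6", "2"])],
    )


def interlocking_graph():
    """Two partially overlapping deletions."""
    return build_graph(
        {"1": "A", "2": "C", "3": "T", "4": "G", "5": "A"},
        [("GRCh38", ["1", "2", "3", "4", "5"]),
         ("w1", ["1", "4", "5"]),
         ("w2", ["1", "2", "5"])],
    )


TAXONOMY_GRAPHS = {
    "properly_triallelic": properly_triallelic_graph,
    "overlapping": overlapping_graph,
    "nested": nested_graph,
    "interlocking": interlocking_graph,
}
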