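"""Pinch-point superbubbles and multiallelic classification.

A superbubble is delimited by an entry and an exit *anchor* — nodes at
which every haplotype aligns: reference-path nodes visited exactly
once, in consistent orientation, by every walk spanning the locus.
Consecutive anchors bound a bubble when at least one variant edge lies
between them.  Every non-terminal variant edge with linear positions
belongs to exactly one superbubble.

Triallelic (two-variant-edge) bubbles are classified as properly
triallelic, overlapping, nested, or interlocking from the endpoint
degrees within the bubble subgraph and from branch-point/end-node
coincidences; bubbles are additionally labelled insertion (entry and
exit tree-adjacent), deletion (entry and exit joined by a variant
edge), or neither.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .errors import NotApplicableError
from .graph_core import BidirectedGraph
from .reference_tree import ReferenceTree
from .variant_catalog import call_variants


@dataclass
class Superbubble:
    entry: str
    exit: str
    interior: set = field(default_factory=set)
    variant_edges: list = field(default_factory=list)
    alleles: list = field(default_factory=list)  # distinct entry->exit subpaths
    ref_allele: tuple | None = None

    @property
    def nodes(self) -> set:
        return self.interior | {self.entry, self.exit}

    @property
    def n_alt_alleles(self) -> int:
        return sum(1 for a in self.alleles if a != self.ref_allele)

    def __repr__(self) -> str:
        return (
            f"Superbubble({self.entry}..{self.exit}, "
            f"{len(self.variant_edges)} variant edges, "
            f"{self.n_alt_alleles} alt alleles)"
        )


def detect_superbubbles(
    graph: BidirectedGraph,
    tree: ReferenceTree,
    variants: list | None = None,
) -> list:
    """Anchor-delimited superbubbles containing >=1 variant edge."""
    if variants is None:
        variants = call_variants(graph, tree)
    ref_path = tree.reference_path
    if not ref_path:
        return []
    pos = tree.position
    node_len = {n: len(graph.nodes[n]) for n in ref_path}

    # --- candidate anchors: reference nodes at which every spanning walk
    # aligns exactly once, in tree orientation -------------------------
    anchors = []
    visit_stats = _walk_visit_stats(graph, tree)
    for r in ref_path:
        p_start = pos[r] - node_len[r] + 1
        ok = True
        for lo, hi, visits in visit_stats:
            if lo <= p_start - 1 and hi >= pos[r] + 1:  # walk spans r
                if visits.get(r) != (1, tree.orientation[r]):
                    ok = False
                    break
        if ok:
            anchors.append(r)

    # --- safety net: no anchor may sit strictly inside a variant edge's
    # position interval ------------------------------------------------
    killed = set()
    for v in variants:
        pu, pv = v.pos_pair
        if pu == -1 or pv == -1:
            continue
        lo, hi = min(pu, pv), max(pu, pv)
        for a in anchors:
            if lo < pos[a] < hi:
                killed.add(a)
    anchors = [a for a in anchors if a not in killed]
    if len(anchors) < 2:
        return []

    # --- assign variant edges to consecutive anchor intervals ---------
    anchor_pos = [pos[a] for a in anchors]
    bubbles = [Superbubble(anchors[i], anchors[i + 1]) for i in range(len(anchors) - 1)]
    unplaced = []
    for v in variants:
        pu, pv = v.pos_pair
        if pu == -1 or pv == -1:
            unplaced.append(v)
            continue
        lo, hi = min(pu, pv), max(pu, pv)
        i = _rightmost_at_most(anchor_pos, lo)
        if lo == hi and i is not None and anchor_pos[i] == lo:
            # point interval at an anchor: belongs to the bubble it opens
            i = min(i, len(bubbles) - 1)
        if i is None or i >= len(bubbles) or anchor_pos[i + 1] < hi:
            unplaced.append(v)
            continue
        bubbles[i].variant_edges.append(v)
    if unplaced:
        warnings.warn(
            f"{len(unplaced)} variant edges outside the anchored coordinate "
            "range were not assigned to a superbubble",
            stacklevel=2,
        )

    # --- alleles and interiors from walk subpaths ----------------------
    anchor_index = {a: i for i, a in enumerate(anchors)}
    for walk in graph.walks:
        is_ref = walk.sample == graph.reference_name
        last_anchor = None  # (bubble idx boundary, step idx)
        for idx, step in enumerate(walk.steps):
            if step.node_id not in anchor_index:
                continue
            if last_anchor is not None:
                i_prev, j_prev = last_anchor
                i_cur = anchor_index[step.node_id]
                if abs(i_cur - i_prev) == 1:
                    b = bubbles[min(i_prev, i_cur)]
                    sub = walk.steps[j_prev + 1: idx]
                    if i_cur < i_prev:  # traversed exit -> entry: flip
                        sub = [s.reverse() for s in reversed(sub)]
                    key = tuple(sub)
                    if key not in b.alleles:
                        b.alleles.append(key)
                    if is_ref:
                        b.ref_allele = key
                    b.interior.update(s.node_id for s in sub)
            last_anchor = (anchor_index[step.node_id], idx)

    # --- position-based fallback for nodes no walk visits ---------------
    placed = set()
    for b in bubbles:
        placed |= b.nodes
    for n in graph.nodes:
        if n in placed or n in anchor_index or pos[n] == -1:
            continue
        on_ref = tree.on_reference(n)
        for i, b in enumerate(bubbles):
            lo, hi = anchor_pos[i], anchor_pos[i + 1]
            if (lo < pos[n] < hi) or (not on_ref and lo <= pos[n] <= hi):
                b.interior.add(n)
                break

    return [b for b in bubbles if b.variant_edges]


def _walk_visit_stats(graph: BidirectedGraph, tree: ReferenceTree) -> list:
    """Per non-reference walk: (coverage lo, hi, {ref node -> (count, orient)})."""
    stats = []
    for walk in graph.walks:
        if walk.sample == graph.reference_name:
            continue
        visits: dict = {}
        anchored = []
        for node_id, orientation in walk.steps:
            p = tree.position[node_id]
            if p != -1:
                anchored.append(p)
            if tree.on_reference(node_id):
                count, _ = visits.get(node_id, (0, orientation))
                visits[node_id] = (
                    count + 1,
                    orientation if count == 0 else "conflict",
                )
        if anchored:
            stats.append((min(anchored), max(anchored), visits))
    return stats


def _rightmost_at_most(sorted_vals: list, x: int):
    """Index of the rightmost value <= x, or None."""
    lo, hi = 0, len(sorted_vals) - 1
    best = None
    while lo <= hi:
        mid = (lo + hi) // 2
        if sorted_vals[mid] <= x:
            best = mid
            lo = mid + 1
        else:
            hi = mid - 1
    return best


# ---------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------

def _bubble_degree(bubble: Superbubble, graph: BidirectedGraph, node: str) -> int:
    """Total edge degree (tree + variant) of ``node`` within the bubble
    subgraph."""
    nodes = bubble.nodes
    deg = 0
    for e in graph.edges_at(node):
        a, b = e.node_ids
        if a in nodes and b in nodes:
            deg += 1
    return deg


def classify_triallelic(
    bubble: Superbubble, tree: ReferenceTree, graph: BidirectedGraph | None = None
) -> str:
    """Label a two-variant superbubble.

    * properly_triallelic — both entry and exit have degree three;
    * overlapping — exactly one of them has degree three;
    * nested — one variant edge branches at the entry *and* lands on
      the exit;
    * interlocking — one variant edge branches at the entry and the
      other lands on the exit.
    """
    if len(bubble.variant_edges) != 2:
        raise NotApplicableError(
            f"bubble has {len(bubble.variant_edges)} variant edges, need 2"
        )
    if graph is None:
        graph = tree.graph
    deg3 = [
        _bubble_degree(bubble, graph, bubble.entry) == 3,
        _bubble_degree(bubble, graph, bubble.exit) == 3,
    ]
    if all(deg3):
        return "properly_triallelic"
    if any(deg3):
        return "overlapping"
    v1, v2 = bubble.variant_edges
    for v in (v1, v2):
        if v.branch_point == bubble.entry and v.v == bubble.exit:
            return "nested"
    for va, vb in ((v1, v2), (v2, v1)):
        if va.branch_point == bubble.entry and vb.v == bubble.exit:
            return "interlocking"
    return "unclassified"


def classify_indel_superbubble(bubble: Superbubble, tree: ReferenceTree) -> str:
    """'insertion' when entry and exit are tree-adjacent, 'deletion'
    when they are joined by a variant edge, else 'neither'."""
    tree_adjacent = any(
        set(e.node_ids) == {bubble.entry, bubble.exit} for e in tree.tree_edges
    )
    variant_adjacent = any(
        set(e.node_ids) == {bubble.entry, bubble.exit}
        for e in (v.edge for v in bubble.variant_edges)
    )
    if tree_adjacent and variant_adjacent:
        warnings.warn(
            f"bubble {bubble.entry}..{bubble.exit} is both tree- and "
            "variant-adjacent; labelling deletion",
            stacklevel=2,
        )
        return "deletion"
    if variant_adjacent:
        return "deletion"
    if tree_adjacent:
        return "insertion"
    return "neither"


def bubble_summary(bubbles: list, tree: ReferenceTree | None = None) -> pd.DataFrame:
    """Per-bubble summary table.

    Checks the multiallelic implication — a bubble with more than one
    alternative allele must contain more than one variant edge — and
    raises AssertionError when it fails.
    """
    rows = []
    for b in bubbles:
        if b.n_alt_alleles > 1 and len(b.variant_edges) <= 1:
            raise AssertionError(
                f"bubble {b.entry}..{b.exit} has {b.n_alt_alleles} alternative "
                f"alleles but only {len(b.variant_edges)} variant edge(s)"
            )
        indel_class = classify_indel_superbubble(b, tree) if tree else "."
        rows.append(
            {
                "entry": b.entry,
                "exit": b.exit,
                "n_variant_edges": len(b.variant_edges),
                "n_alt_alleles": b.n_alt_alleles,
                "indel_class": indel_class,
                "n_non_reference": sum(
                    1 for v in b.variant_edges if v.non_reference
                ),
                "n_interior_nodes": len(b.interior),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "entry", "exit", "n_variant_edges", "n_alt_alleles",
            "indel_class", "n_non_reference", "n_interior_nodes",
        ],
    )
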