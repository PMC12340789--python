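"""Variant edges: alleles, positions, typing and annotation.

Every graph edge absent from the reference tree is a candidate variant.
A non-inversion variant edge, read in walk-traversal direction as
(u, v), has a *branch point* — the lowest common ancestor of u and v in
the reference tree.  Its reference allele is the tree path from the
branch point to v (excluding both); its alternative allele is the tree
path from the branch point to u (excluding the branch point, including
u).  Sequences are read in tree orientation, so reverse-oriented nodes
contribute their reverse complement.

Variant edges fall into seven mutually exclusive types:

==============  =====================================================
deletion        u is a tree ancestor of v (forward skip); empty ALT
duplication     v is a tree ancestor of u (backward return); empty REF
insertion       crossing edge whose reference allele is empty
SNP             crossing edge, both alleles length 1
MNP             crossing edge, equal allele lengths > 1
replacement     any other crossing edge
inversion       edge joining opposite node orientations (no alleles)
==============  =====================================================

Variants whose two alleles are identical (degenerate) and variants
whose branch point or target node is a terminus (terminal edges) are
excluded from the catalog.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import edlib

from .errors import ConsistencyError, NotApplicableError
from .graph_core import (
    FORWARD,
    HEAD,
    REVERSE,
    TAIL,
    BidirectedEdge,
    BidirectedGraph,
    node_sort_key,
)
from .reference_tree import ReferenceTree

SMALL_LARGE_THRESHOLD = 50  # bp of combined allele length
NIA_MIN_ALLELE_LEN = 10

VTYPES = ("SNP", "MNP", "insertion", "deletion", "replacement",
          "duplication", "inversion")


@dataclass
class VariantEdge:
    """A non-tree edge read as a directed traversal (u, v)."""

    edge: BidirectedEdge
    u: str
    v: str
    u_exit_side: str
    v_entry_side: str
    branch_point: str | None
    ref_path: list
    alt_path: list
    ref_seq: str
    alt_seq: str
    vtype: str
    pos_pair: tuple
    non_reference: bool
    tr_motif: str | None = None
    nia: bool = False
    extra: dict = field(default_factory=dict)

    @property
    def combined_allele_length(self) -> int:
        return len(self.ref_seq) + len(self.alt_seq)

    @property
    def size_class(self) -> str:
        if self.vtype == "inversion":
            return "large"
        return "small" if self.combined_allele_length < SMALL_LARGE_THRESHOLD else "large"

    @property
    def id_string(self) -> str:
        """Oriented-node-pair identifier, e.g. ``>1>4``."""
        u_or = ">" if self.u_exit_side == HEAD else "<"
        v_or = ">" if self.v_entry_side == TAIL else "<"
        return f"{u_or}{self.u}{v_or}{self.v}"

    @property
    def node_pair(self) -> tuple:
        return (self.u, self.v)

    def __repr__(self) -> str:
        return f"VariantEdge({self.id_string}, {self.vtype})"


# ---------------------------------------------------------------------
# elemental operations
# ---------------------------------------------------------------------

def branch_point(tree: ReferenceTree, u: str, v: str) -> str:
    """Branch point (lowest common ancestor) of a non-inversion edge."""
    if tree.orientation[u] != tree.orientation[v]:
        raise NotApplicableError(
            f"({u},{v}) joins opposite orientations; inversion edges have "
            "no branch point"
        )
    return tree.lca(u, v)


def alleles(tree: ReferenceTree, u: str, v: str) -> tuple:
    """(ref_seq, alt_seq) for the non-inversion variant edge (u, v)."""
    w = tree.lca(u, v)
    if tree.is_terminus(w) or tree.is_terminus(v):
        raise NotApplicableError(
            f"({u},{v}) is a terminal edge; alleles are undefined"
        )
    ref_path = tree.path_down(w, v)[1:-1]
    alt_path = tree.path_down(w, u)[1:]
    return tree.path_sequence(ref_path), tree.path_sequence(alt_path)


def classify(variant: VariantEdge) -> str:
    """Assign exactly one of the seven variant types."""
    if variant.vtype == "inversion":
        return "inversion"
    if variant.branch_point == variant.u:
        return "deletion"
    if variant.branch_point == variant.v:
        return "duplication"
    ref, alt = variant.ref_seq, variant.alt_seq
    if ref == "":
        return "insertion"
    if len(ref) == len(alt) == 1:
        return "SNP"
    if len(ref) == len(alt):
        return "MNP"
    return "replacement"


def _upstream_context(tree: ReferenceTree, node: str, k: int) -> str:
    """Last <=k bases of the tree sequence ending at ``node`` (inclusive)."""
    parts = []
    total = 0
    n = node
    while n is not None and total < k:
        s = tree.oriented_sequence(n)
        parts.append(s)
        total += len(s)
        entry = tree.parent.get(n)
        n = entry[0] if entry else None
    return "".join(reversed(parts))[-k:]


def _downstream_context(tree: ReferenceTree, node: str, k: int) -> str:
    """First <=k bases of the tree sequence starting at ``node``.

    Follows the reference path where possible, otherwise a sole child.
    """
    parts = []
    total = 0
    n = node
    while n is not None and total < k:
        s = tree.oriented_sequence(n)
        parts.append(s)
        total += len(s)
        kids = [c for c in tree.children.get(n, []) if not tree.is_terminus(c)]
        on_ref = [c for c in kids if tree.on_reference(c)]
        if on_ref:
            n = on_ref[0]
        elif len(kids) == 1:
            n = kids[0]
        else:
            n = None
    return "".join(parts)[:k]


def annotate_repeat(variant: VariantEdge, tree: ReferenceTree) -> str | None:
    """Tandem-repeat motif of an indel, or None.

    The indel is a local tandem repeat when its non-empty allele equals
    ``s * n`` for some motif s and the flanking tree sequence of length
    ``|s|`` — upstream of the branch point, or downstream of v — equals
    s.  The minimal such period is reported, preferring an upstream
    match over a downstream one.
    """
    if variant.vtype not in ("insertion", "deletion"):
        return None
    allele = variant.alt_seq if variant.vtype == "insertion" else variant.ref_seq
    if not allele:
        return None
    n = len(allele)
    for p in range(1, n + 1):
        if n % p != 0:
            continue
        s = allele[:p]
        if s * (n // p) != allele:
            continue
        if _upstream_context(tree, variant.branch_point, p) == s:
            return s
        if _downstream_context(tree, variant.v, p) == s:
            return s
    return None


def flag_nia(variants) -> list:
    """Nearly-identical-allele flags: allele pairs >=10 bp apiece whose
    edit distance is exactly one (substitution or 1-bp indel)."""
    flags = []
    for v in variants:
        nia = False
        if min(len(v.ref_seq), len(v.alt_seq)) >= NIA_MIN_ALLELE_LEN:
            d = edlib.align(v.ref_seq, v.alt_seq, task="distance")["editDistance"]
            nia = d == 1
        v.nia = nia
        flags.append(nia)
    return flags


# ---------------------------------------------------------------------
# catalog construction
# ---------------------------------------------------------------------

def _observed_readings(graph: BidirectedGraph, tree: ReferenceTree) -> dict:
    """edge -> set of directed readings ((u, exit), (v, entry)) seen in walks."""
    seen: dict = {}
    for walk in graph.walks:
        for a, b in walk.step_pairs():
            e = BidirectedEdge.from_steps(a, b)
            from_end = (a.node_id, HEAD if a.orientation == FORWARD else TAIL)
            to_end = (b.node_id, TAIL if b.orientation == FORWARD else HEAD)
            seen.setdefault(e, set()).add((from_end, to_end))
        start, end = tree.terminus_edges_for_walk(walk)
        first, last = walk.steps[0], walk.steps[-1]
        seen.setdefault(start, set()).add(
            ((tree.terminus_nodes[1], HEAD),
             (first.node_id, TAIL if first.orientation == FORWARD else HEAD))
        )
        seen.setdefault(end, set()).add(
            ((last.node_id, HEAD if last.orientation == FORWARD else TAIL),
             (tree.terminus_nodes[2], TAIL))
        )
    return seen


def _fallback_reading(tree: ReferenceTree, edge: BidirectedEdge):
    """Directed reading for an edge no walk traverses: prefer the
    reading that enters v the way the tree does."""
    readings = edge.readings()
    def consistent(reading):
        (_, _), (v, sv) = reading
        if tree.is_terminus(v):
            return False
        want = TAIL if tree.orientation[v] == FORWARD else HEAD
        return sv == want
    good = [r for r in readings if consistent(r)]
    pick = good[0] if len(good) == 1 else min(
        readings, key=lambda r: (node_sort_key(r[1][0]), r[1][1])
    )
    return pick


def call_variants(graph: BidirectedGraph, tree: ReferenceTree) -> list:
    """One VariantEdge per retained non-tree edge.

    Excludes terminal edges (branch point or v is a terminus) and
    degenerate variants (identical alleles).  The result is sorted by
    position; its order defines the genotype-vector layout downstream.
    """
    if tree.graph is not graph:
        raise ConsistencyError("tree was not built on this graph")
    observed = _observed_readings(graph, tree)
    ref_visited = tree.reference_visited_nodes()
    variants = []
    for edge in tree.variant_candidate_edges():
        readings = sorted(observed.get(edge, ()))
        if not readings:
            readings = [_fallback_reading(tree, edge)]
        elif len(readings) > 1:
            warnings.warn(
                f"edge {edge} traversed in both directions by walks; "
                "emitting one variant per surviving direction",
                stacklevel=2,
            )
        for (u, su), (v, sv) in readings:
            variant = _make_variant(tree, edge, u, su, v, sv, ref_visited)
            if variant is not None:
                variants.append(variant)
    flag_nia(variants)
    variants.sort(
        key=lambda x: (x.pos_pair[0], x.pos_pair[1], node_sort_key(x.u),
                       node_sort_key(x.v))
    )
    return variants


def _make_variant(tree, edge, u, su, v, sv, ref_visited):
    if tree.is_terminus(v) or tree.is_terminus(u):
        return None
    rel_u = FORWARD if su == HEAD else REVERSE
    rel_v = FORWARD if sv == TAIL else REVERSE
    inversion = (rel_u == tree.orientation[u]) != (rel_v == tree.orientation[v])
    pos_pair = (tree.position[u], tree.position[v])
    non_reference = v not in ref_visited
    if inversion:
        return VariantEdge(
            edge=edge, u=u, v=v, u_exit_side=su, v_entry_side=sv,
            branch_point=None, ref_path=[], alt_path=[],
            ref_seq="", alt_seq="", vtype="inversion",
            pos_pair=pos_pair, non_reference=non_reference,
        )
    w = tree.lca(u, v)
    if tree.is_terminus(w):
        return None  # terminal edge
    ref_path = tree.path_down(w, v)[1:-1]
    alt_path = tree.path_down(w, u)[1:]
    ref_seq = tree.path_sequence(ref_path)
    alt_seq = tree.path_sequence(alt_path)
    if ref_seq == alt_seq:
        return None  # degenerate alleles
    variant = VariantEdge(
        edge=edge, u=u, v=v, u_exit_side=su, v_entry_side=sv,
        branch_point=w, ref_path=ref_path, alt_path=alt_path,
        ref_seq=ref_seq, alt_seq=alt_seq, vtype="",
        pos_pair=pos_pair, non_reference=non_reference,
    )
    variant.vtype = classify(variant)
    variant.tr_motif = annotate_repeat(variant, tree)
    return variant
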