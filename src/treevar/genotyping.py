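"""Genotypes of haplotype walks over the variant catalog.

The genotype of a walk is the number of times it visits each variant
edge (in either direction — the bidirected edge, not a strand of it).
Together with its endpoints, the genotype identifies a walk uniquely:
two walks with equal endpoints and equal genotype vectors are the same
walk, and a walk can be reconstructed from its genotype.

Per-haplotype genotype columns use:

* CA — visits of the variant edge itself;
* CR — visits of the corresponding *reference edge*, the last tree edge
  of the reference-allele path, i.e. the tree edge (parent(v), v);
* GT — 1 when CA > 0, 0 when CA = 0 and CR > 0, missing when both
  counts are missing.  When a haplotype covers the locus but routes
  through a third allele (CA = CR = 0), GT is reported as missing while
  the zero counts are kept.

A haplotype's counts are missing at a variant when the variant's
position interval falls entirely outside the haplotype's linear
coverage (the union over its contigs of [min, max] anchored positions).
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

from .errors import (
    AmbiguousWalkError,
    ConsistencyError,
    NoWalkError,
    NotApplicableError,
)
from .graph_core import (
    FORWARD,
    HEAD,
    REVERSE,
    TAIL,
    BidirectedGraph,
    OrientedNode,
    Walk,
)
from .reference_tree import ReferenceTree
from .variant_catalog import VariantEdge

MAX_RECONSTRUCT_VISITS = 6


# ---------------------------------------------------------------------
# traversal counting
# ---------------------------------------------------------------------

def walk_edge_counts(walk: Walk, tree: ReferenceTree) -> Counter:
    """Undirected visit counts per edge, including the walk's two
    terminus wiring edges (a walk start counts as arriving from the
    source binode, a walk end as departing into the sink binode)."""
    counts: Counter = Counter(walk.edges())
    start, end = tree.terminus_edges_for_walk(walk)
    counts[start] += 1
    counts[end] += 1
    return counts


def genotype_walk(walk: Walk, variants: list, tree: ReferenceTree) -> list:
    """Visit counts of each variant edge by the walk, in catalog order."""
    for step in walk.steps:
        if step.node_id not in tree.parent:
            raise ConsistencyError(
                f"walk visits node {step.node_id!r} unknown to the tree"
            )
    counts = walk_edge_counts(walk, tree)
    return [counts.get(v.edge, 0) for v in variants]


def reference_edge_count(walk: Walk, variant: VariantEdge, tree: ReferenceTree) -> int:
    """Visits by the walk of the tree edge (parent(v), v)."""
    parent_entry = tree.parent[variant.v]
    if parent_entry is None:
        return 0
    counts = walk_edge_counts(walk, tree)
    return counts.get(parent_entry[1], 0)


# ---------------------------------------------------------------------
# coverage and missingness
# ---------------------------------------------------------------------

@dataclass
class CoverageInterval:
    """Linear-reference coverage of one haplotype."""

    haplotype: tuple
    intervals: list = field(default_factory=list)  # closed [lo, hi] pairs
    components: set = field(default_factory=set)  # for position-less regions

    def covers(self, lo: int, hi: int) -> bool:
        return any(a <= hi and lo <= b for a, b in self.intervals)


def coverage_intervals(
    graph: BidirectedGraph, tree: ReferenceTree, haplotype: tuple,
    component_of: dict | None = None,
) -> CoverageInterval:
    if component_of is None:
        component_of = graph.component_index()
    cov = CoverageInterval(haplotype=haplotype)
    for walk in graph.walks:
        if walk.haplotype != haplotype:
            continue
        anchored = [
            tree.position[s.node_id]
            for s in walk.steps
            if tree.position[s.node_id] != -1
        ]
        if anchored:
            cov.intervals.append((min(anchored), max(anchored)))
        cov.components.update(component_of[s.node_id] for s in walk.steps)
    return cov


def missingness(
    variant: VariantEdge, coverage: CoverageInterval,
    component_of: dict | None = None,
) -> bool:
    """True when the variant lies entirely outside the haplotype's
    coverage, so its counts cannot be observed."""
    pu, pv = variant.pos_pair
    if pu == -1 and pv == -1:
        if component_of is None:
            return True
        return component_of[variant.u] not in coverage.components
    lo, hi = sorted(p for p in (pu, pv) if p != -1), None
    lo, hi = lo[0], lo[-1]
    return not coverage.covers(lo, hi)


# ---------------------------------------------------------------------
# genotype table
# ---------------------------------------------------------------------

@dataclass
class GenotypeRecord:
    """Per-haplotype counts and aggregates for one variant."""

    variant: VariantEdge
    per_haplotype: dict  # haplotype -> (cr|None, ca|None, gt|None)
    rc: int = 0
    ac: int = 0

    @property
    def an(self) -> int:
        return self.rc + self.ac


def build_genotypes(
    graph: BidirectedGraph, tree: ReferenceTree, variants: list
) -> list:
    """GenotypeRecord per variant, haplotypes in walk order."""
    component_of = graph.component_index()
    haplotypes = graph.haplotypes()
    hap_counts = {h: Counter() for h in haplotypes}
    for walk in graph.walks:
        hap_counts[walk.haplotype].update(walk_edge_counts(walk, tree))
    coverages = {
        h: coverage_intervals(graph, tree, h, component_of) for h in haplotypes
    }
    records = []
    for variant in variants:
        parent_entry = tree.parent[variant.v]
        ref_edge = parent_entry[1] if parent_entry else None
        per_hap = {}
        rc = ac = 0
        for h in haplotypes:
            if missingness(variant, coverages[h], component_of):
                per_hap[h] = (None, None, None)
                continue
            cr = hap_counts[h].get(ref_edge, 0) if ref_edge is not None else 0
            ca = hap_counts[h].get(variant.edge, 0)
            gt = 1 if ca > 0 else (0 if cr > 0 else None)
            per_hap[h] = (cr, ca, gt)
            rc += cr
            ac += ca
        records.append(
            GenotypeRecord(variant=variant, per_haplotype=per_hap, rc=rc, ac=ac)
        )
    return records


# ---------------------------------------------------------------------
# walk reconstruction
# ---------------------------------------------------------------------

def reconstruct_walk(
    genotype: list,
    start: str,
    end: str,
    tree: ReferenceTree,
    variants: list,
    sample: str = "reconstructed",
) -> Walk:
    """Rebuild the walk with the given genotype and endpoints.

    A walk visiting exactly one variant edge (u, v) must follow the
    unique tree path start→u, the edge, then the tree path v→end;
    the general case searches over visit orders (and edge strands) and
    returns the unique valid walk.  Infeasible genotypes raise
    NoWalkError; genotypes realised by more than one distinct walk
    raise AmbiguousWalkError.
    """
    if len(genotype) != len(variants):
        raise ConsistencyError("genotype length does not match catalog size")
    visits = []
    for count, variant in zip(genotype, variants):
        if count < 0:
            raise NoWalkError("negative visit count")
        visits.extend([variant] * count)
    if len(visits) > MAX_RECONSTRUCT_VISITS:
        raise NotApplicableError(
            "walk reconstruction is restricted to genotypes with at most "
            f"{MAX_RECONSTRUCT_VISITS} variant-edge visits"
        )

    solutions = set()
    for order in set(itertools.permutations(range(len(visits)))):
        ordered = [visits[i] for i in order]
        reading_choices = [v.edge.readings() for v in ordered]
        for strands in itertools.product(*reading_choices):
            steps = _compose(tree, start, end, ordered, strands)
            if steps is None:
                continue
            candidate = Walk(sample, 0, steps)
            if _counts_match(candidate, tree, genotype, variants):
                solutions.add(tuple(candidate.steps))
    if not solutions:
        raise NoWalkError(
            f"no walk from {start} to {end} realises genotype {genotype}"
        )
    if len(solutions) > 1:
        raise AmbiguousWalkError(
            f"{len(solutions)} distinct walks realise genotype {genotype}"
        )
    return Walk(sample, 0, list(solutions.pop()))


def _counts_match(walk, tree, genotype, variants) -> bool:
    counts = Counter(walk.edges())  # interior visits only; no terminus edges
    return [counts.get(v.edge, 0) for v in variants] == genotype


def _compose(tree, start, end, ordered, strands):
    """Try to realise one visit order; returns OrientedNode steps or None."""
    anchors = [start]
    for (u_end, v_end) in strands:
        anchors.extend((u_end[0], v_end[0]))
    anchors.append(end)

    annotated: list = []  # (node, enter|None, exit|None)
    for i in range(0, len(anchors) - 1, 2):
        a, b = anchors[i], anchors[i + 1]
        seg = tree.directed_path(a, b)
        if any(tree.is_terminus(n) for n, _, _ in seg):
            return None
        if i > 0:
            (_, su), (v, sv) = strands[i // 2 - 1][0], strands[i // 2 - 1][1]
            n0, enter0, exit0 = seg[0]
            seg[0] = (n0, sv, exit0)
        if i + 2 < len(anchors):
            (u, su), _ = strands[i // 2]
            nl, enterl, _ = seg[-1]
            seg[-1] = (nl, enterl, su)
        annotated.extend(seg)

    # validity: interior steps must pass through (enter != exit)
    for idx, (n, enter, exit_) in enumerate(annotated):
        interior = 0 < idx < len(annotated) - 1
        if interior and (enter is None or exit_ is None or enter == exit_):
            return None
        if not interior and enter is not None and exit_ is not None and enter == exit_:
            return None
    steps = []
    for n, enter, exit_ in annotated:
        if enter is not None:
            orientation = FORWARD if enter == TAIL else REVERSE
        elif exit_ is not None:
            orientation = FORWARD if exit_ == HEAD else REVERSE
        else:
            orientation = FORWARD
        steps.append(OrientedNode(n, orientation))
    return steps
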