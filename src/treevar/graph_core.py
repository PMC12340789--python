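"""Bidirected pangenome graph model and GFA I/O.

A pangenome graph is *bidirected*: every node (a DNA segment) has two
sides, a ``tail`` (the 5' end of the forward strand) and a ``head`` (the
3' end).  Traversing a node forward means entering at the tail and
leaving at the head; traversing it in reverse means the opposite, and
the emitted sequence is the reverse complement.  An edge joins two
node-sides, so the GFA links ``L 1 + 2 +`` and ``L 2 - 1 -`` describe
the same physical adjacency and canonicalise to the same object here.

Haplotypes are walks: ordered, orientation-annotated node traversals
(GFA W-lines; P-lines are accepted as unphased walks).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

from .errors import (
    ConfigurationError,
    GfaParseError,
    ReferentialIntegrityError,
    WalkConsistencyError,
)

FORWARD = "+"
REVERSE = "-"
HEAD = "head"
TAIL = "tail"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")
_WALK_STEP_RE = re.compile(r"([><])([^><\s]+)")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def node_sort_key(node_id: str):
    """Numeric-aware ordering: '2' before '10', digits before names."""
    return (0, int(node_id), "") if node_id.isdigit() else (1, 0, node_id)


def exit_side(orientation: str) -> str:
    """Side through which a traversal *leaves* a node."""
    return HEAD if orientation == FORWARD else TAIL


def entry_side(orientation: str) -> str:
    """Side through which a traversal *enters* a node."""
    return TAIL if orientation == FORWARD else HEAD


class OrientedNode(NamedTuple):
    node_id: str
    orientation: str  # FORWARD or REVERSE

    def reverse(self) -> "OrientedNode":
        return OrientedNode(
            self.node_id, REVERSE if self.orientation == FORWARD else FORWARD
        )

    def __str__(self) -> str:
        return (">" if self.orientation == FORWARD else "<") + self.node_id


End = tuple  # (node_id, side)


def _end_key(end: End):
    return (node_sort_key(end[0]), end[1])


@dataclass(frozen=True)
class BidirectedEdge:
    """Unordered pair of node-sides; symmetric under strand flipping."""

    end_a: End
    end_b: End

    def __post_init__(self):
        a, b = self.end_a, self.end_b
        if _end_key(a) > _end_key(b):
            object.__setattr__(self, "end_a", b)
            object.__setattr__(self, "end_b", a)

    # -- constructors -------------------------------------------------
    @classmethod
    def from_link(cls, a_id: str, a_or: str, b_id: str, b_or: str) -> "BidirectedEdge":
        """Build from GFA L-line semantics: leave ``a``, enter ``b``."""
        return cls((a_id, exit_side(a_or)), (b_id, entry_side(b_or)))

    @classmethod
    def from_steps(cls, u: OrientedNode, v: OrientedNode) -> "BidirectedEdge":
        return cls.from_link(u.node_id, u.orientation, v.node_id, v.orientation)

    # -- accessors ----------------------------------------------------
    @property
    def node_ids(self) -> tuple:
        return (self.end_a[0], self.end_b[0])

    def is_self_loop(self) -> bool:
        return self.end_a[0] == self.end_b[0]

    def touches(self, node_id: str) -> bool:
        return node_id in self.node_ids

    def other_end(self, end: End) -> End:
        if end == self.end_a:
            return self.end_b
        if end == self.end_b:
            return self.end_a
        raise KeyError(f"{end} is not an end of {self}")

    def readings(self) -> list:
        """Both directed readings ((u, exit), (v, entry)) of the edge."""
        out = [(self.end_a, self.end_b)]
        if self.end_a != self.end_b:
            out.append((self.end_b, self.end_a))
        return out

    def link_fields(self) -> tuple:
        """(a_id, a_or, b_id, b_or) in GFA L-line semantics."""
        (a, sa), (b, sb) = self.end_a, self.end_b
        return (a, FORWARD if sa == HEAD else REVERSE, b, FORWARD if sb == TAIL else REVERSE)

    def __str__(self) -> str:
        a, oa, b, ob = self.link_fields()
        return f"{a}{oa}--{b}{ob}"


@dataclass
class Walk:
    """One haplotype contig as an oriented traversal of graph nodes."""

    sample: str
    hap_index: int
    steps: list  # list[OrientedNode]
    seq_name: str = "0"
    contig_index: int = 0

    def __post_init__(self):
        self.steps = [OrientedNode(*s) for s in self.steps]
        if not self.steps:
            raise ValueError("a walk must have at least one step")

    @property
    def haplotype(self) -> tuple:
        return (self.sample, self.hap_index)

    def step_pairs(self) -> Iterator[tuple]:
        return zip(self.steps, self.steps[1:])

    def edges(self) -> Iterator[BidirectedEdge]:
        for u, v in self.step_pairs():
            yield BidirectedEdge.from_steps(u, v)

    def sequence(self, graph: "BidirectedGraph") -> str:
        """Concatenated (orientation-respecting) sequence of the walk."""
        parts = []
        for node_id, orientation in self.steps:
            seq = graph.nodes[node_id]
            parts.append(seq if orientation == FORWARD else reverse_complement(seq))
        return "".join(parts)

    def to_w_line(self) -> str:
        walk_str = "".join(str(s) for s in self.steps)
        return f"W\t{self.sample}\t{self.hap_index}\t{self.seq_name}\t*\t*\t{walk_str}"


@dataclass
class BidirectedGraph:
    """Nodes with sequences, bidirected edges, and named haplotype walks."""

    reference_name: str = "GRCh38"
    nodes: dict = field(default_factory=dict)  # node_id -> uppercase ACGTN
    edges: set = field(default_factory=set)
    walks: list = field(default_factory=list)

    # -- construction -------------------------------------------------
    def add_node(self, node_id: str, seq: str) -> None:
        seq = seq.upper()
        if not set(seq) <= _VALID_BASES:
            warnings.warn(
                f"segment {node_id}: non-ACGTN bases mapped to N", stacklevel=2
            )
            seq = "".join(b if b in _VALID_BASES else "N" for b in seq)
        self.nodes[node_id] = seq

    def add_edge(self, edge: BidirectedEdge) -> None:
        for nid in edge.node_ids:
            if nid not in self.nodes:
                raise ReferentialIntegrityError(
                    f"edge {edge} references unknown segment {nid!r}"
                )
        self.edges.add(edge)

    def add_link(self, a_id: str, a_or: str, b_id: str, b_or: str) -> BidirectedEdge:
        edge = BidirectedEdge.from_link(a_id, a_or, b_id, b_or)
        self.add_edge(edge)
        return edge

    def add_walk(self, walk: Walk, validate: bool = True) -> None:
        for node_id, _ in walk.steps:
            if node_id not in self.nodes:
                raise ReferentialIntegrityError(
                    f"walk {walk.sample}#{walk.hap_index} visits unknown "
                    f"segment {node_id!r}"
                )
        if validate:
            for u, v in walk.step_pairs():
                e = BidirectedEdge.from_steps(u, v)
                if e not in self.edges:
                    raise WalkConsistencyError(
                        f"walk {walk.sample}#{walk.hap_index}: no edge for "
                        f"step pair {u} -> {v}"
                    )
        self.walks.append(walk)

    # -- queries ------------------------------------------------------
    @property
    def samples(self) -> list:
        seen: dict = {}
        for w in self.walks:
            seen.setdefault(w.sample, None)
        return list(seen)

    def reference_walks(self) -> list:
        return [w for w in self.walks if w.sample == self.reference_name]

    def haplotypes(self) -> list:
        """Distinct (sample, hap_index) pairs in walk order."""
        seen: dict = {}
        for w in self.walks:
            seen.setdefault(w.haplotype, None)
        return list(seen)

    def edges_at(self, node_id: str) -> list:
        return [e for e in self.edges if e.touches(node_id)]

    def side_index(self) -> dict:
        """Map (node_id, side) -> list of incident edges (loops twice)."""
        idx: dict = {}
        for e in self.edges:
            idx.setdefault(e.end_a, []).append(e)
            idx.setdefault(e.end_b, []).append(e)
        return idx

    def adjacency(self) -> dict:
        adj: dict = {n: set() for n in self.nodes}
        for e in self.edges:
            a, b = e.node_ids
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def component_nodes(self, seed_node: str) -> set:
        if seed_node not in self.nodes:
            raise KeyError(seed_node)
        adj = self.adjacency()
        seen = {seed_node}
        stack = [seed_node]
        while stack:
            for m in adj[stack.pop()]:
                if m not in seen:
                    seen.add(m)
                    stack.append(m)
        return seen

    def component_index(self) -> dict:
        """node_id -> component label (smallest member id)."""
        adj = self.adjacency()
        label: dict = {}
        for start in sorted(self.nodes, key=node_sort_key):
            if start in label:
                continue
            comp = [start]
            seen = {start}
            while comp:
                n = comp.pop()
                label[n] = start
                for m in adj[n]:
                    if m not in seen:
                        seen.add(m)
                        comp.append(m)
        return label

    def total_sequence_length(self) -> int:
        return sum(len(s) for s in self.nodes.values())

    def validate(self) -> None:
        for e in self.edges:
            for nid in e.node_ids:
                if nid not in self.nodes:
                    raise ReferentialIntegrityError(f"edge {e} dangling at {nid!r}")
        names = {w.sample for w in self.walks}
        if self.walks and self.reference_name not in names:
            raise ConfigurationError(
                f"reference sample {self.reference_name!r} has no walk"
            )


# ---------------------------------------------------------------------
# GFA I/O
# ---------------------------------------------------------------------

def _parse_walk_string(text: str, lineno: int) -> list:
    steps = []
    consumed = 0
    for m in _WALK_STEP_RE.finditer(text):
        consumed += len(m.group(0))
        steps.append(
            OrientedNode(m.group(2), FORWARD if m.group(1) == ">" else REVERSE)
        )
    if not steps or consumed != len(text):
        raise GfaParseError(f"line {lineno}: malformed walk string {text!r}")
    return steps


def read_gfa(path, reference_name: str) -> BidirectedGraph:
    """Load a GFA 1.0/1.1 file (S, L, W, P lines) into a BidirectedGraph.

    W-lines are preferred; P-lines are mapped to walks with
    ``hap_index`` 0.  The designated linear-reference sample must own at
    least one walk.
    """
    graph = BidirectedGraph(reference_name=reference_name)
    links: list = []
    pending_walks: list = []
    n_s_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            tag = fields[0]
            if tag == "H":
                continue
            if tag == "S":
                if len(fields) < 3:
                    raise GfaParseError(f"line {lineno}: S-line needs id and sequence")
                seq = "" if fields[2] == "*" else fields[2]
                graph.add_node(fields[1], seq)
                n_s_lines += 1
            elif tag == "L":
                if len(fields) < 5 or fields[2] not in "+-" or fields[4] not in "+-":
                    raise GfaParseError(f"line {lineno}: malformed L-line")
                links.append((lineno, fields[1], fields[2], fields[3], fields[4]))
            elif tag == "W":
                if len(fields) < 7:
                    raise GfaParseError(f"line {lineno}: W-line needs 7 fields")
                try:
                    hap = int(fields[2])
                except ValueError as exc:
                    raise GfaParseError(
                        f"line {lineno}: haplotype index {fields[2]!r} not an integer"
                    ) from exc
                steps = _parse_walk_string(fields[6], lineno)
                pending_walks.append(
                    (lineno, Walk(fields[1], hap, steps, seq_name=fields[3]))
                )
            elif tag == "P":
                if len(fields) < 3:
                    raise GfaParseError(f"line {lineno}: P-line needs name and steps")
                steps = []
                for item in fields[2].split(","):
                    if len(item) < 2 or item[-1] not in "+-":
                        raise GfaParseError(
                            f"line {lineno}: malformed P-line step {item!r}"
                        )
                    steps.append(OrientedNode(item[:-1], item[-1]))
                pending_walks.append((lineno, Walk(fields[1], 0, steps)))
            # other record types are ignored
    if n_s_lines == 0:
        raise GfaParseError(f"{path}: no S-lines found")
    for lineno, a, oa, b, ob in links:
        for nid in (a, b):
            if nid not in graph.nodes:
                raise ReferentialIntegrityError(
                    f"line {lineno}: L-line references unknown segment {nid!r}"
                )
        graph.add_link(a, oa, b, ob)
    contig_counter: dict = {}
    for lineno, walk in sorted(pending_walks, key=lambda t: t[0]):
        key = walk.haplotype
        walk.contig_index = contig_counter.get(key, 0)
        contig_counter[key] = walk.contig_index + 1
        try:
            graph.add_walk(walk)
        except WalkConsistencyError as exc:
            raise WalkConsistencyError(f"line {lineno}: {exc}") from exc
    if graph.walks and reference_name not in {w.sample for w in graph.walks}:
        raise ConfigurationError(
            f"reference sample {reference_name!r} not present among walks"
        )
    return graph


def write_gfa(graph: BidirectedGraph, path) -> None:
    """Emit the graph as GFA 1.1 (S, L, W lines)."""
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.1\n")
        for node_id in sorted(graph.nodes, key=node_sort_key):
            seq = graph.nodes[node_id] or "*"
            fh.write(f"S\t{node_id}\t{seq}\n")
        for edge in sorted(graph.edges, key=lambda e: (_end_key(e.end_a), _end_key(e.end_b))):
            a, oa, b, ob = edge.link_fields()
            fh.write(f"L\t{a}\t{oa}\t{b}\t{ob}\t0M\n")
        for walk in graph.walks:
            fh.write(walk.to_w_line() + "\n")


# ---------------------------------------------------------------------
# Subgraph extraction
# ---------------------------------------------------------------------

def extract_component(graph: BidirectedGraph, seed_node: str) -> BidirectedGraph:
    """Connected component containing ``seed_node``.

    Walks are restricted to maximal sub-walks inside the component.
    """
    keep = graph.component_nodes(seed_node)
    out = BidirectedGraph(reference_name=graph.reference_name)
    for nid in keep:
        out.nodes[nid] = graph.nodes[nid]
    for e in graph.edges:
        if all(n in keep for n in e.node_ids):
            out.edges.add(e)
    for walk in graph.walks:
        for piece_index, piece in enumerate(_split_on(walk.steps, keep)):
            out.add_walk(
                Walk(
                    walk.sample,
                    walk.hap_index,
                    piece,
                    seq_name=f"{walk.seq_name}.{piece_index}",
                ),
                validate=False,
            )
    return out


def _split_on(steps: list, keep: set) -> Iterator[list]:
    run: list = []
    for step in steps:
        if step.node_id in keep:
            run.append(step)
        elif run:
            yield run
            run = []
    if run:
        yield run


# ---------------------------------------------------------------------
# Visualisation-oriented simplification
# ---------------------------------------------------------------------

def simplify(
    graph: BidirectedGraph,
    variant_edges: Iterable,
    min_combined_allele_len: int,
) -> BidirectedGraph:
    """Prune short variant edges, delete tips, contract linear paths.

    ``variant_edges`` is the catalog computed on this graph; an entry is
    dropped from the output graph when the combined length of its two
    alleles is below ``min_combined_allele_len`` (inversions count as
    length 0).  Tips — dead-end branches off the reference path, not
    contained in any cycle — are then removed by iterative pruning of
    degree-<=1 nodes, and maximal non-branching runs are contracted into
    single nodes carrying the concatenated sequence.
    """
    if min_combined_allele_len < 0:
        raise ValueError("min_combined_allele_len must be >= 0")
    pruned = {
        ve.edge
        for ve in variant_edges
        if ve.combined_allele_length < min_combined_allele_len
    }
    nodes = dict(graph.nodes)
    edges = set(graph.edges) - pruned

    ref_nodes: set = set()
    for w in graph.reference_walks():
        ref_nodes.update(s.node_id for s in w.steps)

    # --- tip removal (never touches the reference path) ---
    changed = True
    while changed:
        changed = False
        deg: dict = {n: 0 for n in nodes}
        for e in edges:
            a, b = e.node_ids
            deg[a] += 1
            if b != a:
                deg[b] += 1
        for n in list(nodes):
            if n not in ref_nodes and deg.get(n, 0) <= 1:
                del nodes[n]
                edges = {e for e in edges if not e.touches(n)}
                changed = True

    # --- path contraction ---
    side_count: dict = {}
    for e in edges:
        side_count[e.end_a] = side_count.get(e.end_a, 0) + 1
        side_count[e.end_b] = side_count.get(e.end_b, 0) + 1

    def contractible(e: BidirectedEdge) -> bool:
        return (
            not e.is_self_loop()
            and side_count.get(e.end_a, 0) == 1
            and side_count.get(e.end_b, 0) == 1
        )

    c_edges = {e for e in edges if contractible(e)}
    # per (node, side) the unique contractible edge, if any
    c_at: dict = {}
    for e in c_edges:
        c_at[e.end_a] = e
        c_at[e.end_b] = e

    chains, consumed = _build_chains(nodes, c_at)
    chain_of: dict = {}
    for chain in chains:
        for idx, (nid, orient) in enumerate(chain):
            chain_of[nid] = (chain, idx, orient)

    def chain_id(chain) -> str:
        return "_".join(nid for nid, _ in chain)

    out = BidirectedGraph(reference_name=graph.reference_name)
    for chain in chains:
        seq = "".join(
            nodes[nid] if orient == FORWARD else reverse_complement(nodes[nid])
            for nid, orient in chain
        )
        out.nodes[chain_id(chain)] = seq

    def map_end(end: End) -> End:
        nid, side = end
        chain, idx, orient = chain_of[nid]
        # non-contracted edges attach at free chain-end sides
        if idx == 0 and side == entry_side(orient):
            return (chain_id(chain), TAIL)
        if idx == len(chain) - 1 and side == exit_side(orient):
            return (chain_id(chain), HEAD)
        # single-node chain, or loop back onto a chain end
        return (chain_id(chain), side if orient == FORWARD
                else (TAIL if side == HEAD else HEAD))

    for e in edges - consumed:
        out.edges.add(BidirectedEdge(map_end(e.end_a), map_end(e.end_b)))

    for walk in graph.walks:
        _remap_walk(walk, nodes, edges, chain_of, chain_id, out)
    return out


def _build_chains(nodes: dict, c_at: dict) -> tuple:
    """Maximal runs of nodes joined by contractible edges.

    Each chain is a list of (node_id, orientation) such that traversing
    the chain forward visits each node with the given orientation.
    Fully contractible cycles are broken at the smallest node id (the
    cycle-closing edge survives as a self-loop on the contracted node).
    Returns (chains, set of contracted edges).
    """
    chains = []
    assigned: set = set()
    consumed: set = set()

    def extend(nid: str, ahead_side: str) -> list:
        run = []
        while True:
            edge = c_at.get((nid, ahead_side))
            if edge is None:
                break
            nxt, side = edge.other_end((nid, ahead_side))
            if nxt in assigned or nxt == nid:
                break
            orient = FORWARD if side == TAIL else REVERSE
            assigned.add(nxt)
            consumed.add(edge)
            run.append((nxt, orient))
            nid, ahead_side = nxt, exit_side(orient)
        return run

    for nid in sorted(nodes, key=node_sort_key):
        if nid in assigned:
            continue
        assigned.add(nid)
        forward_run = extend(nid, HEAD)
        backward_run = extend(nid, TAIL)
        back = [(n, REVERSE if o == FORWARD else FORWARD) for n, o in backward_run]
        chains.append(list(reversed(back)) + [(nid, FORWARD)] + forward_run)
    return chains, consumed


def _remap_walk(walk, nodes, edges, chain_of, chain_id, out: BidirectedGraph) -> None:
    # split walk where nodes/edges were deleted
    fragments: list = []
    run: list = []
    for i, step in enumerate(walk.steps):
        if step.node_id not in nodes:
            if run:
                fragments.append(run)
            run = []
            continue
        if run:
            prev = run[-1]
            if BidirectedEdge.from_steps(prev, step) not in edges:
                fragments.append(run)
                run = []
        run.append(step)
    if run:
        fragments.append(run)

    piece_index = 0
    for frag in fragments:
        supersteps: list = []
        i = 0
        while i < len(frag):
            nid, o = frag[i]
            chain, idx, orient = chain_of[nid]
            L = len(chain)
            same = o == orient
            if same and idx == 0 and _matches(frag, i, chain, forward=True):
                supersteps.append(OrientedNode(chain_id(chain), FORWARD))
                i += L
            elif not same and idx == L - 1 and _matches(frag, i, chain, forward=False):
                supersteps.append(OrientedNode(chain_id(chain), REVERSE))
                i += L
            else:
                i += 1  # partial chain coverage at a fragment boundary: trim
        for piece in _valid_superstep_runs(supersteps, out):
            out.add_walk(
                Walk(walk.sample, walk.hap_index, piece,
                     seq_name=f"{walk.seq_name}.{piece_index}"),
                validate=False,
            )
            piece_index += 1


def _matches(frag, i, chain, forward: bool) -> bool:
    L = len(chain)
    if i + L > len(frag):
        return False
    order = chain if forward else list(reversed(chain))
    for k, (nid, orient) in enumerate(order):
        want = orient if forward else (REVERSE if orient == FORWARD else FORWARD)
        if frag[i + k].node_id != nid or frag[i + k].orientation != want:
            return False
    return True


def _valid_superstep_runs(steps: list, graph: BidirectedGraph) -> Iterator[list]:
    run: list = []
    for step in steps:
        if run and BidirectedEdge.from_steps(run[-1], step) not in graph.edges:
            yield run
            run = []
        run.append(step)
    if run:
        yield run
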