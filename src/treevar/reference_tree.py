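"""Bidirected spanning reference tree anchored on the linear reference.

The reference tree contains *all* nodes of the pangenome graph but only
a subset of its edges.  It is rooted at a synthetic source terminus and
seeded with the full linear-reference walk, so the linear reference is
always a branch of the tree.  Remaining nodes are attached breadth
first, preferring candidate edges traversed by the most haplotype
walks, so that common haplotypes tend to follow tree paths and common
alleles become "reference".

Four terminus nodes (two binodes, empty sequences) anchor walk starts,
walk ends, and disconnected components.  Non-tree edges incident to a
terminus are *terminal edges* and are excluded from the variant catalog
downstream.

The tree induces, for every node: a parent pointer, a depth, an
orientation (forward/reverse, from the side through which the tree
enters the node), and a position — the 1-based linear-reference
coordinate of the last base of the node's deepest reference ancestor,
or -1 when the root path contains no reference node.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field

from .errors import ConfigurationError, EmptyGraphError
from .graph_core import (
    FORWARD,
    HEAD,
    REVERSE,
    TAIL,
    BidirectedEdge,
    BidirectedGraph,
    Walk,
    entry_side,
    exit_side,
    node_sort_key,
    reverse_complement,
)

SOURCE_A = "__source_1"
SOURCE_B = "__source_2"
SINK_A = "__sink_1"
SINK_B = "__sink_2"
TERMINUS_NODES = (SOURCE_A, SOURCE_B, SINK_A, SINK_B)

_SIDE_RANK = {HEAD: 0, TAIL: 1}


@dataclass
class TerminusAnchor:
    """Synthetic empty-sequence binode anchoring walk boundaries."""

    role: str  # "source" or "sink"
    binode: tuple  # pair of node ids


@dataclass
class ReferenceTree:
    graph: BidirectedGraph
    root: str = SOURCE_A
    parent: dict = field(default_factory=dict)  # node -> (parent, edge) | None
    children: dict = field(default_factory=dict)
    tree_edges: set = field(default_factory=set)
    orientation: dict = field(default_factory=dict)
    depth: dict = field(default_factory=dict)
    position: dict = field(default_factory=dict)
    ref_distance: dict = field(default_factory=dict)  # tree edges to ref path
    reference_path: list = field(default_factory=list)
    terminus_nodes: tuple = TERMINUS_NODES
    wiring_edges: set = field(default_factory=set)  # all synthetic edges
    _ref_set: set = field(default_factory=set)
    _tin: dict = field(default_factory=dict)
    _tout: dict = field(default_factory=dict)

    # -- basic queries -------------------------------------------------
    def is_terminus(self, node_id: str) -> bool:
        return node_id in self.terminus_nodes

    def on_reference(self, node_id: str) -> bool:
        return node_id in self._ref_set

    def orient(self, u: str) -> str:
        """Orientation implied by the root->u tree path."""
        return self.orientation[u]

    def node_position(self, u: str) -> int:
        """Linear-reference coordinate (last base) of the deepest
        reference node on the root->u tree path; -1 if none."""
        return self.position[u]

    def parent_edge(self, u: str):
        entry = self.parent[u]
        return None if entry is None else entry[1]

    def is_ancestor(self, a: str, b: str) -> bool:
        """True iff a is an ancestor of b (a == b counts)."""
        return self._tin[a] <= self._tin[b] and self._tout[b] <= self._tout[a]

    def lca(self, a: str, b: str) -> str:
        """Lowest common ancestor in the reference tree."""
        da, db = self.depth[a], self.depth[b]
        while da > db:
            a = self.parent[a][0]
            da -= 1
        while db > da:
            b = self.parent[b][0]
            db -= 1
        while a != b:
            a = self.parent[a][0]
            b = self.parent[b][0]
        return a

    # -- paths ---------------------------------------------------------
    def path_up(self, node: str, ancestor: str) -> list:
        """Nodes from ``node`` up to ``ancestor``, both inclusive."""
        out = [node]
        while node != ancestor:
            node = self.parent[node][0]
            out.append(node)
        return out

    def path_down(self, ancestor: str, node: str) -> list:
        return list(reversed(self.path_up(node, ancestor)))

    def tree_path(self, a: str, b: str) -> list:
        """Unique tree path a..b (inclusive)."""
        w = self.lca(a, b)
        up = self.path_up(a, w)
        down = self.path_down(w, b)
        return up + down[1:]

    def tree_edge_between(self, x: str, y: str) -> BidirectedEdge:
        if self.parent.get(y) and self.parent[y][0] == x:
            return self.parent[y][1]
        if self.parent.get(x) and self.parent[x][0] == y:
            return self.parent[x][1]
        raise KeyError(f"{x} and {y} are not tree-adjacent")

    def oriented_sequence(self, node: str) -> str:
        seq = self._node_seq(node)
        return seq if self.orientation[node] == FORWARD else reverse_complement(seq)

    def path_sequence(self, nodes) -> str:
        return "".join(self.oriented_sequence(n) for n in nodes)

    def directed_path(self, a: str, b: str) -> list:
        """Tree path a..b as [(node, enter_side|None, exit_side|None)].

        Side annotations come from the tree edges along the path; walk
        validity (enter != exit at interior nodes) is for the caller to
        check, since bidirected tree paths need not be valid walks.
        """
        nodes = self.tree_path(a, b)
        steps = []
        for i, n in enumerate(nodes):
            enter = exit_ = None
            if i > 0:
                e = self.tree_edge_between(nodes[i - 1], n)
                enter = self._side_of(e, n, other=nodes[i - 1])
            if i + 1 < len(nodes):
                e = self.tree_edge_between(n, nodes[i + 1])
                exit_ = self._side_of(e, n, other=nodes[i + 1])
            steps.append((n, enter, exit_))
        return steps

    @staticmethod
    def _side_of(edge: BidirectedEdge, node: str, other: str) -> str:
        (na, sa), (nb, sb) = edge.end_a, edge.end_b
        if na == node and (nb == other or na == nb):
            return sa
        if nb == node:
            return sb
        raise KeyError(f"{node} not on edge {edge}")

    def _node_seq(self, node: str) -> str:
        if node in self.terminus_nodes:
            return ""
        return self.graph.nodes[node]

    # -- reference geometry ---------------------------------------------
    def reference_length(self) -> int:
        return self.position[self.reference_path[-1]] if self.reference_path else 0

    def reference_sequence(self) -> str:
        return self.path_sequence(self.reference_path)

    def reference_visited_nodes(self) -> set:
        return set(self._ref_set)

    # -- variant-edge candidates ----------------------------------------
    def variant_candidate_edges(self) -> set:
        """All non-tree edges, including non-tree terminus wiring edges."""
        return (set(self.graph.edges) | self.wiring_edges) - self.tree_edges

    def graph_non_tree_edges(self) -> set:
        return set(self.graph.edges) - self.tree_edges

    def terminus_edges_for_walk(self, walk: Walk) -> tuple:
        """(start wiring edge, end wiring edge) for a walk."""
        first, last = walk.steps[0], walk.steps[-1]
        start = BidirectedEdge(
            (SOURCE_B, HEAD), (first.node_id, entry_side(first.orientation))
        )
        end = BidirectedEdge(
            (last.node_id, exit_side(last.orientation)), (SINK_A, TAIL)
        )
        return start, end

    # -- export ----------------------------------------------------------
    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("node_id\tparent\torientation\tdepth\tposition\n")
            for n in sorted(self.parent, key=node_sort_key):
                p = self.parent[n]
                fh.write(
                    f"{n}\t{p[0] if p else '.'}\t{self.orientation[n]}"
                    f"\t{self.depth[n]}\t{self.position[n]}\n"
                )


def build_tree(graph: BidirectedGraph, tie_break_rng=None) -> ReferenceTree:
    """Construct the reference tree for ``graph``.

    The tree is seeded with the linear-reference walk (rooted at the
    source terminus) and grown by best-first expansion: among edges with
    exactly one endpoint in the tree, prefer the edge traversed by the
    most haplotype walks; remaining ties go to the smaller numeric node
    id and the head side before the tail side.  Passing a random
    generator as ``tie_break_rng`` randomises tie resolution instead
    (the *number* of resulting variant edges is invariant to this
    choice, only their identity changes).
    """
    if not graph.nodes:
        raise EmptyGraphError("cannot build a reference tree on an empty graph")
    for t in TERMINUS_NODES:
        if t in graph.nodes:
            raise ConfigurationError(f"segment name {t!r} is reserved")
    ref_walks = graph.reference_walks()
    if not ref_walks:
        raise ConfigurationError(
            f"no walk for reference sample {graph.reference_name!r}"
        )
    if len(ref_walks) > 1:
        raise ConfigurationError(
            "the linear reference must be a single contiguous walk"
        )
    ref_walk = ref_walks[0]
    ref_ids = [s.node_id for s in ref_walk.steps]
    if len(set(ref_ids)) != len(ref_ids):
        raise ConfigurationError(
            "reference walk revisits a node; cyclic references are not supported"
        )

    tree = ReferenceTree(graph=graph)
    tree.reference_path = ref_ids
    tree._ref_set = set(ref_ids)

    # ---- terminus wiring ------------------------------------------------
    src_internal = BidirectedEdge((SOURCE_A, HEAD), (SOURCE_B, TAIL))
    snk_internal = BidirectedEdge((SINK_A, HEAD), (SINK_B, TAIL))
    tree.wiring_edges = {src_internal, snk_internal}
    for walk in graph.walks:
        start, end = tree.terminus_edges_for_walk(walk)
        tree.wiring_edges.update((start, end))

    # ---- seed: root, source binode, reference branch, sink binode -------
    def attach(child: str, parent: str, edge) -> None:
        tree.parent[child] = (parent, edge)
        tree.children.setdefault(parent, []).append(child)
        tree.children.setdefault(child, [])
        if edge is not None:
            tree.tree_edges.add(edge)
            side = ReferenceTree._side_of(edge, child, other=parent)
            tree.orientation[child] = FORWARD if side == TAIL else REVERSE
        else:
            tree.orientation[child] = FORWARD

    tree.parent[SOURCE_A] = None
    tree.children[SOURCE_A] = []
    tree.orientation[SOURCE_A] = FORWARD
    attach(SOURCE_B, SOURCE_A, src_internal)
    ref_start_edge, _ = tree.terminus_edges_for_walk(ref_walk)
    attach(ref_ids[0], SOURCE_B, ref_start_edge)
    for u, v in ref_walk.step_pairs():
        attach(v.node_id, u.node_id, BidirectedEdge.from_steps(u, v))
    _, ref_end_edge = tree.terminus_edges_for_walk(ref_walk)
    attach(SINK_A, ref_ids[-1], ref_end_edge)
    attach(SINK_B, SINK_A, snk_internal)

    # ---- edge weights: haplotype walk traversals ------------------------
    # A candidate edge is weighted by the number of walk traversals that
    # *enter the prospective child* through it, so that each node is
    # attached in the orientation in which haplotypes actually reach it;
    # the undirected traversal count breaks the first tie.
    weight: dict = {}
    enter_count: dict = {}
    for walk in graph.walks:
        for a, b in walk.step_pairs():
            e = BidirectedEdge.from_steps(a, b)
            weight[e] = weight.get(e, 0) + 1
            b_end = (b.node_id, entry_side(b.orientation))
            enter_count[(e, b_end)] = enter_count.get((e, b_end), 0) + 1
        start, end = tree.terminus_edges_for_walk(walk)
        weight[start] = weight.get(start, 0) + 1
        weight[end] = weight.get(end, 0) + 1
        first = walk.steps[0]
        f_end = (first.node_id, entry_side(first.orientation))
        enter_count[(start, f_end)] = enter_count.get((start, f_end), 0) + 1

    # ---- best-first expansion ------------------------------------------
    side_index = graph.side_index()
    for e in tree.wiring_edges:
        for end in (e.end_a, e.end_b):
            if end[0] not in TERMINUS_NODES:
                side_index.setdefault(end, []).append(e)

    counter = itertools.count()
    heap: list = []

    def tie_key(edge: BidirectedEdge, child_end, parent_end):
        if tie_break_rng is not None:
            return (tie_break_rng.random(),)
        return (
            node_sort_key(child_end[0]),
            node_sort_key(parent_end[0]),
            _SIDE_RANK[parent_end[1]],
            _SIDE_RANK[child_end[1]],
        )

    def push_candidates(node: str) -> None:
        for side in (TAIL, HEAD):
            for e in side_index.get((node, side), []):
                try:
                    other, _ = e.other_end((node, side))
                except KeyError:
                    continue
                if other in tree.parent or other in TERMINUS_NODES:
                    continue
                child_end = e.end_a if e.end_a[0] == other else e.end_b
                parent_end = e.other_end(child_end)
                heapq.heappush(
                    heap,
                    (
                        -enter_count.get((e, child_end), 0),
                        -weight.get(e, 0),
                        tie_key(e, child_end, parent_end),
                        next(counter),
                        child_end,
                        parent_end,
                        e,
                    ),
                )

    for n in list(tree.parent):
        if n not in TERMINUS_NODES:
            push_candidates(n)

    def drain() -> None:
        while heap:
            _, _, _, _, child_end, parent_end, e = heapq.heappop(heap)
            child = child_end[0]
            if child in tree.parent:
                continue
            attach(child, parent_end[0], e)
            push_candidates(child)

    drain()

    # ---- anchor leftover components to the source terminus --------------
    remaining = [n for n in graph.nodes if n not in tree.parent]
    while remaining:
        comp_seed = min(remaining, key=node_sort_key)
        anchor_edge = BidirectedEdge((SOURCE_B, HEAD), (comp_seed, TAIL))
        tree.wiring_edges.add(anchor_edge)
        attach(comp_seed, SOURCE_B, anchor_edge)
        push_candidates(comp_seed)
        drain()
        remaining = [n for n in graph.nodes if n not in tree.parent]

    _finalise(tree)
    return tree


def _finalise(tree: ReferenceTree) -> None:
    """Depths, positions, reference distances and Euler intervals."""
    ref_pos: dict = {}
    total = 0
    for n in tree.reference_path:
        total += len(tree.graph.nodes[n])
        ref_pos[n] = total

    clock = itertools.count()
    stack = [(tree.root, 0, -1, -1, False)]
    while stack:
        node, depth, last_ref, rdist, done = stack.pop()
        if done:
            tree._tout[node] = next(clock)
            continue
        tree.depth[node] = depth
        if node in ref_pos:
            last_ref, rdist = ref_pos[node], 0
        elif rdist >= 0:
            rdist += 1
        tree.position[node] = last_ref
        tree.ref_distance[node] = rdist
        tree._tin[node] = next(clock)
        stack.append((node, depth, last_ref, rdist, True))
        for child in reversed(tree.children.get(node, [])):
            stack.append((child, depth + 1, last_ref, rdist, False))
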