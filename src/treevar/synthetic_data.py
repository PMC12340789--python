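"""Fixtures and a pangenome simulator with planted ground truth.

The simulator plants non-overlapping mutational events (SNPs, small
indels, large insertions and deletions, inversions, tandem
duplications, an insertion carrying a nested SNP, and interlocking
deletion pairs) on a random reference sequence, then constructs the
graph *exactly*: the reference is split into segments at every event
breakpoint, alternative segments are added, and haplotype walks route
through the events they carry.  Edges are exactly the adjacencies
traversed by the walks, so the emitted graph is consistent by
construction and concatenating any haplotype's walk reproduces the
mutated sequence produced by direct string editing.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .errors import PlacementError
from .graph_core import (
    FORWARD,
    BidirectedEdge,
    BidirectedGraph,
    OrientedNode,
    Walk,
    reverse_complement,
)

_BASES = "ACGT"


# =====================================================================
# toy worked-example fixture
# =====================================================================

def fig1_fixture() -> tuple:
    """An 11-node toy pangenome with three variant edges.

    The reference walk runs 1-2-3-4-5-8-11.  Non-tree edges are exactly
    (1,4) — a forward (deletion) edge, (7,8) — a crossing (replacement)
    edge, and (9,3) — a crossing (insertion) edge; node 3 has two
    incoming edges, one of which becomes the tree edge.  The "green"
    haplotype traverses the insertion and the replacement but not the
    deletion, so its genotype over ((1,4),(7,8),(9,3)) is [0,1,1].  A
    fragmented haplotype (two contigs) weights the intended tree edges
    so the tie-breaks reproduce this tree, and exercises terminal-edge
    exclusion.  The whole graph forms a single superbubble between
    nodes 1 and 8.
    """
    g = BidirectedGraph(reference_name="GRCh38")
    seqs = {
        "1": "A", "2": "CG", "3": "T", "4": "CT", "5": "G",
        "8": "AT", "11": "GG",
        "6": "G", "7": "A", "10": "AC", "9": "GT",
    }
    for nid, seq in seqs.items():
        g.add_node(nid, seq)

    def walk(sample, hap, ids, seq_name="chr"):
        steps = [OrientedNode(i, FORWARD) for i in ids]
        for a, b in zip(steps, steps[1:]):
            g.edges.add(BidirectedEdge.from_steps(a, b))
        g.add_walk(Walk(sample, hap, steps, seq_name=seq_name))

    walk("GRCh38", 0, ["1", "2", "3", "4", "5", "8", "11"])
    walk("green", 0, ["1", "2", "10", "9", "3", "6", "7", "8", "11"])
    walk("delcarrier", 0, ["1", "4", "5", "8", "11"])
    walk("frag", 0, ["1", "2", "10", "9"], seq_name="chr.0")
    walk("frag", 0, ["3", "6", "7"], seq_name="chr.1")

    expected = {
        "n_nodes": 11,
        "green_sample": "green",
        "variant_edges": {
            ("1", "4"): "deletion",
            ("7", "8"): "replacement",
            ("9", "3"): "insertion",
        },
        "green_genotype": {("1", "4"): 0, ("7", "8"): 1, ("9", "3"): 1},
        "alleles": {
            ("1", "4"): ("CGT", ""),
            ("7", "8"): ("CTG", "GA"),
            ("9", "3"): ("", "ACGT"),
        },
        "vcf": {
            ("1", "4"): (1, "ACGT", "A"),
            ("9", "3"): (3, "G", "GACGT"),
            ("7", "8"): (5, "CTG", "GA"),
        },
        "superbubble": ("1", "8"),
        "reference_sequence": "ACGTCTGATGG",
    }
    return g, expected


# =====================================================================
# simulator
# =====================================================================

@dataclass
class SimulationConfig:
    reference_length: int = 10_000
    n_haplotypes: int = 4
    n_snps: int = 20
    n_small_indels: int = 5
    n_large_insertions: int = 0
    n_large_deletions: int = 2
    n_inversions: int = 1
    n_tandem_duplications: int = 0
    n_nested_snp_insertions: int = 1
    n_interlocking_deletion_pairs: int = 0
    walks_per_haplotype: int = 1
    seed: int = 0
    reference_name: str = "GRCh38"

    def __post_init__(self):
        counts = (
            self.n_snps, self.n_small_indels, self.n_large_insertions,
            self.n_large_deletions, self.n_inversions,
            self.n_tandem_duplications, self.n_nested_snp_insertions,
            self.n_interlocking_deletion_pairs,
        )
        if any(c < 0 for c in counts):
            raise ValueError("event counts must be non-negative")


@dataclass
class TruthVariant:
    """Expected call for one planted variant edge (VCF conventions)."""

    vtype: str
    pos: int  # VCF POS
    ref: str
    alt: str
    nr: str = "."
    non_reference: bool = False
    carriers: tuple = ()

    @property
    def key(self) -> tuple:
        return (self.vtype, self.pos)


@dataclass
class TruthCatalog:
    entries: list = field(default_factory=list)
    reference: str = ""
    # (start, end, {hap: replacement}) spans for the string-edit oracle
    spans: list = field(default_factory=list)

    def keys(self) -> list:
        return sorted(e.key for e in self.entries)

    def to_vcf(self, path, ref_length: int, chrom: str = "ref") -> None:
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={chrom},length={ref_length}>\n")
            fh.write(
                '##INFO=<ID=VT,Number=1,Type=String,Description="Planted '
                'variant type">\n'
            )
            fh.write(
                '##INFO=<ID=NR,Number=1,Type=String,Description="Off-reference '
                'reference allele">\n'
            )
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for e in sorted(self.entries, key=lambda e: e.pos):
                fh.write(
                    f"{chrom}\t{e.pos}\t.\t{e.ref}\t{e.alt}\t60\tPASS\t"
                    f"VT={e.vtype};NR={e.nr}\n"
                )


@dataclass
class _Event:
    """A planted event over the half-open reference span [start, end).

    ``routes`` maps a haplotype index to the replacement string for the
    span (None means the haplotype keeps the reference)."""

    kind: str
    start: int
    end: int
    cuts: tuple  # internal breakpoints (includes start/end where needed)
    routes: dict  # hap -> replacement string
    truth: list  # TruthVariant entries
    # graph construction recipe, filled in during build:
    steps_for: dict = field(default_factory=dict)  # hap -> list[OrientedNode]


def _pick_carriers(rng: random.Random, n_haps: int, at_least: int = 1) -> tuple:
    for _ in range(200):
        carriers = tuple(h for h in range(n_haps) if rng.random() < 0.5)
        if at_least <= len(carriers) and (len(carriers) < n_haps or n_haps == 1):
            return carriers
    return tuple(range(min(at_least, n_haps)))


def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(n))


def simulate(config: SimulationConfig) -> tuple:
    """Build (BidirectedGraph, TruthCatalog) from a configuration."""
    rng = random.Random(config.seed)
    L = config.reference_length
    ref = _random_seq(rng, L)
    haps = range(config.n_haplotypes)

    occupied: list = []  # closed interval list with 2 bp guard bands

    def place(span: int) -> int:
        for _ in range(1000):
            p = rng.randrange(10, L - 10 - max(span, 1))
            if all(p - 2 >= e or p + span + 2 <= s for s, e in occupied):
                occupied.append((p, p + max(span, 1)))
                return p
        raise PlacementError(
            f"could not place an event of span {span} in {L} bp"
        )

    events: list = []

    def add(kind, start, end, cuts, routes, truth):
        events.append(_Event(kind, start, end, tuple(cuts), routes, truth))

    # events are placed largest span first, so that small events do not
    # fragment the free space needed by structural ones
    for _ in range(config.n_large_insertions):
        ins = _random_seq(rng, rng.randint(100, 300))
        p = place(0)
        carriers = _pick_carriers(rng, config.n_haplotypes)
        add(
            "insertion", p, p, (p,),
            {h: ins for h in carriers},
            [TruthVariant("insertion", p, ref[p - 1], ref[p - 1] + ins,
                          carriers=carriers)],
        )

    for _ in range(config.n_large_deletions):
        size = rng.randint(150, 400)
        p = place(size)
        carriers = _pick_carriers(rng, config.n_haplotypes)
        add(
            "deletion", p, p + size, (p, p + size),
            {h: "" for h in carriers},
            [TruthVariant("deletion", p, ref[p - 1: p + size], ref[p - 1],
                          carriers=carriers)],
        )

    for _ in range(config.n_inversions):
        size = rng.randint(80, 200)
        p = place(size)
        carriers = _pick_carriers(rng, config.n_haplotypes)
        add(
            "inversion", p, p + size, (p, p + size),
            {h: reverse_complement(ref[p: p + size]) for h in carriers},
            [
                TruthVariant("inversion", p + 1, ".", "<INV>", carriers=carriers),
                TruthVariant("inversion", p + size + 1, ".", "<INV>",
                             carriers=carriers),
            ],
        )

    for _ in range(config.n_tandem_duplications):
        size = rng.randint(20, 60)
        p = place(size)
        m = p + size // 2
        carriers = _pick_carriers(rng, config.n_haplotypes)
        add(
            "tandem_duplication", p, p + size, (p, m, p + size),
            {h: ref[p: p + size] * 2 for h in carriers},
            [TruthVariant("duplication", p + size, ref[p + size - 1],
                          ref[p + size - 1] + ref[m: p + size],
                          carriers=carriers)],
        )

    for _ in range(config.n_nested_snp_insertions):
        if config.n_haplotypes < 3:
            raise PlacementError(
                "a nested SNP needs at least two insertion carriers and one "
                "non-carrier haplotype"
            )
        ins_len = rng.randint(100, 160)
        k = rng.randint(1, ins_len - 2)
        seq_a = _random_seq(rng, ins_len)
        base_a = seq_a[k]
        base_b = rng.choice([b for b in _BASES if b != base_a])
        seq_b = seq_a[:k] + base_b + seq_a[k + 1:]
        p = place(0)
        carriers = _pick_carriers(rng, config.n_haplotypes, at_least=2)
        group_b = tuple(carriers[i] for i in range(1, len(carriers), 2))
        group_a = tuple(h for h in carriers if h not in group_b)
        routes = {h: seq_a for h in group_a}
        routes.update({h: seq_b for h in group_b})
        add(
            "nested_snp_insertion", p, p, (p,), routes,
            [
                TruthVariant("insertion", p, ref[p - 1], ref[p - 1] + seq_a,
                             carriers=carriers),
                TruthVariant("SNP", p + 1, ".", base_b, nr=base_a,
                             non_reference=True, carriers=group_b),
            ],
        )
        events[-1].steps_for["_nested"] = (k, base_a, base_b)  # recipe hint

    for _ in range(config.n_interlocking_deletion_pairs):
        if config.n_haplotypes < 2:
            raise PlacementError("interlocking deletions need two carriers")
        len1 = rng.randint(40, 80)
        a = place(len1 + 60)
        b = a + rng.randint(10, len1 - 10)
        c = a + len1
        d = b + (c - b) + rng.randint(10, 40)
        h1 = rng.randrange(config.n_haplotypes)
        h2 = rng.choice([h for h in haps if h != h1])
        add(
            "interlocking_deletions", a, d, (a, b, c, d),
            {h1: ref[c:d], h2: ref[a:b]},
            [
                TruthVariant("deletion", a, ref[a - 1: c], ref[a - 1],
                             carriers=(h1,)),
                TruthVariant("deletion", b, ref[b - 1: d], ref[b - 1],
                             carriers=(h2,)),
            ],
        )
        events[-1].steps_for["_interlock"] = (h1, h2)

    for _ in range(config.n_small_indels):
        if rng.random() < 0.5:
            size = rng.randint(1, 10)
            p = place(size)
            carriers = _pick_carriers(rng, config.n_haplotypes)
            add(
                "deletion", p, p + size, (p, p + size),
                {h: "" for h in carriers},
                [TruthVariant("deletion", p, ref[p - 1: p + size], ref[p - 1],
                              carriers=carriers)],
            )
        else:
            ins = _random_seq(rng, rng.randint(1, 10))
            p = place(0)
            carriers = _pick_carriers(rng, config.n_haplotypes)
            add(
                "insertion", p, p, (p,),
                {h: ins for h in carriers},
                [TruthVariant("insertion", p, ref[p - 1], ref[p - 1] + ins,
                              carriers=carriers)],
            )

    for _ in range(config.n_snps):
        p = place(1)
        old = ref[p]
        new = rng.choice([b for b in _BASES if b != old])
        carriers = _pick_carriers(rng, config.n_haplotypes)
        add(
            "snp", p, p + 1, (p, p + 1),
            {h: new for h in carriers},
            [TruthVariant("SNP", p + 1, old, new, carriers=carriers)],
        )

    events.sort(key=lambda e: e.start)
    graph = _build_graph(config, ref, events)
    truth = TruthCatalog(
        entries=[t for e in events for t in e.truth],
        reference=ref,
        spans=[(e.start, e.end, dict(e.routes)) for e in events],
    )
    return graph, truth


def _build_graph(config: SimulationConfig, ref: str, events: list) -> BidirectedGraph:
    L = len(ref)
    breakpoints = sorted({0, L, *(c for e in events for c in e.cuts)})
    graph = BidirectedGraph(reference_name=config.reference_name)
    seg_at: dict = {}  # start coordinate -> (node_id, end)
    segments = []
    for i, (s, e) in enumerate(zip(breakpoints, breakpoints[1:]), start=1):
        nid = str(i)
        graph.add_node(nid, ref[s:e])
        seg_at[s] = (nid, e)
        segments.append((s, e, nid))
    next_id = len(segments) + 1

    def new_node(seq: str) -> str:
        nonlocal next_id
        nid = str(next_id)
        next_id += 1
        graph.add_node(nid, seq)
        return nid

    def ref_steps(s: int, e: int) -> list:
        out = []
        while s < e:
            nid, end = seg_at[s]
            out.append(OrientedNode(nid, FORWARD))
            s = end
        return out

    # per-event alternative nodes and per-haplotype step recipes
    for ev in events:
        recipe = ev.steps_for
        hint = recipe.pop("_nested", None)
        interlock_hint = recipe.pop("_interlock", None)
        if ev.kind == "snp":
            alt = new_node(next(iter(ev.routes.values())))
            for h in ev.routes:
                recipe[h] = [OrientedNode(alt, FORWARD)]
        elif ev.kind in ("insertion",):
            alt = new_node(next(iter(ev.routes.values())))
            for h in ev.routes:
                recipe[h] = [OrientedNode(alt, FORWARD)]
        elif ev.kind == "deletion":
            for h in ev.routes:
                recipe[h] = []
        elif ev.kind == "inversion":
            inv = ref_steps(ev.start, ev.end)
            flipped = [s.reverse() for s in reversed(inv)]
            for h in ev.routes:
                recipe[h] = flipped
        elif ev.kind == "tandem_duplication":
            once = ref_steps(ev.start, ev.end)
            for h in ev.routes:
                recipe[h] = once + once
        elif ev.kind == "nested_snp_insertion":
            k, base_a, base_b = hint
            seq_a = next(s for s in ev.routes.values() if s[k] == base_a)
            pre = new_node(seq_a[:k])
            node_a = new_node(base_a)
            node_b = new_node(base_b)
            post = new_node(seq_a[k + 1:])
            for h, s in ev.routes.items():
                mid = node_a if s[k] == base_a else node_b
                recipe[h] = [
                    OrientedNode(pre, FORWARD),
                    OrientedNode(mid, FORWARD),
                    OrientedNode(post, FORWARD),
                ]
        elif ev.kind == "interlocking_deletions":
            a, b, c, d = ev.cuts
            h1, h2 = interlock_hint
            recipe[h1] = ref_steps(c, d)  # carries deletion [a, c)
            recipe[h2] = ref_steps(a, b)  # carries deletion [b, d)
        else:  # pragma: no cover
            raise ValueError(f"unknown event kind {ev.kind!r}")

    # walks: reference, then each haplotype routed through its events
    ref_walk_steps = ref_steps(0, L)
    graph_edges_from = lambda steps: [
        BidirectedEdge.from_steps(x, y) for x, y in zip(steps, steps[1:])
    ]
    all_walks = [Walk(config.reference_name, 0, ref_walk_steps, seq_name="ref")]
    for h in range(config.n_haplotypes):
        steps: list = []
        cursor = 0
        for ev in events:
            steps.extend(ref_steps(cursor, ev.start))
            if h in ev.routes:
                steps.extend(ev.steps_for[h])
            else:
                steps.extend(ref_steps(ev.start, ev.end))
            cursor = ev.end
        steps.extend(ref_steps(cursor, L))
        sample = f"sim{h}"
        n_pieces = max(1, config.walks_per_haplotype)
        for j, piece in enumerate(_chunk(steps, n_pieces)):
            all_walks.append(Walk(sample, 0, piece, seq_name=f"hap.{j}"))

    for w in all_walks:
        for e in graph_edges_from(w.steps):
            graph.edges.add(e)
    for w in all_walks:
        graph.add_walk(w)
    return graph


def _chunk(steps: list, n: int) -> list:
    if n <= 1 or len(steps) <= n:
        return [steps]
    size = (len(steps) + n - 1) // n
    return [steps[i: i + size] for i in range(0, len(steps), size)]


def haplotype_sequence(truth: TruthCatalog, h: int) -> str:
    """String-edit oracle: apply the replacement spans carried by
    haplotype ``h`` directly to the reference string, independently of
    the graph."""
    ref = truth.reference
    parts = []
    cursor = 0
    for start, end, routes in sorted(truth.spans):
        parts.append(ref[cursor:start])
        parts.append(routes.get(h, ref[start:end]))
        cursor = end
    parts.append(ref[cursor:])
    return "".join(parts)


def simulate_to_files(config: SimulationConfig, gfa_path, truth_vcf_path) -> tuple:
    """Run the simulator and write the GFA and the truth VCF."""
    from .graph_core import write_gfa

    graph, truth = simulate(config)
    write_gfa(graph, gfa_path)
    ref_len = sum(
        len(graph.nodes[s.node_id]) for s in graph.reference_walks()[0].steps
    )
    truth.to_vcf(truth_vcf_path, ref_len)
    return graph, truth
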