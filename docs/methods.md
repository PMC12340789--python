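# Methods

## The model: variants against a reference tree

A pangenome graph G is bidirected: each node carries a DNA segment with
two sides (*tail* = 5' of the forward strand, *head* = 3'), an edge
joins two node-sides, and a haplotype is a walk — an ordered,
orientation-annotated node traversal whose concatenated (and, for
reverse steps, reverse-complemented) sequences spell the assembly.

`treevar` defines variants against a **reference tree** T: a bidirected
spanning tree that contains *every* node of G but only a subset of its
edges, and that contains the designated linear-reference walk as a
branch. Every edge of G absent from T is a **variant edge**: a walk
that traverses it carries an alternative allele; a walk that reaches
the same node through the tree carries the reference allele. Because T
is a tree, paths between nodes are unique, so alleles and genotypes are
well defined, and the set of variant edges behaves like a basis: two
walks with equal endpoints and equal variant-edge visit counts are the
same walk (checked exhaustively on small graphs in the test suite).

For a non-inversion variant edge read in walk direction as (u, v):

* **branch point** w = the lowest common ancestor of u and v in T;
* **reference allele** = tree path w → v, excluding w and v;
* **alternative allele** = tree path w → u, excluding w, including u;
* **position pair** = (pos(u), pos(v)), where pos(x) is the 1-based
  coordinate of the last base of the deepest linear-reference node on
  the root → x tree path (−1 when no such node exists).

Types partition as: deletion (u an ancestor of v), duplication (v an
ancestor of u), and for crossing edges insertion (empty reference
allele), SNP (1 bp / 1 bp), MNP (equal length > 1), else replacement.
An edge whose two endpoint traversals disagree with the tree
orientations on exactly one side is an **inversion**; inversions carry
no branch point or alleles, are reported individually (a simple
inversion event produces a pair of them), and are classed `large`.
Edges whose branch point or target v is a terminus (below) are
*terminal* and excluded, as are degenerate edges whose two alleles are
identical strings.

## Tree construction

The exact growth order of the spanning tree is a free design choice —
any spanning tree that contains the reference branch yields a valid
catalog with the same number of variant edges. `treevar` uses:

1. Four terminus nodes (two empty-sequence binodes) are created; the
   source binode is the root. Wiring edges connect the source to every
   walk's first node and every walk's last node to the sink, so walk
   boundaries and reference-free components are anchored. Only the
   reference walk's two terminus edges are forced into the tree.
2. The tree is seeded with the full reference walk.
3. Remaining nodes are attached best-first. A candidate edge (one
   endpoint in the tree) is preferred by, in order:
   (a) the number of walk traversals that **enter the prospective child
   through that edge** — so each node is adopted in the orientation in
   which haplotypes actually reach it;
   (b) the undirected walk-traversal count of the edge;
   (c) smaller numeric child id, smaller parent id, head side before
   tail side.
   Criterion (a) matters: with purely undirected weights, the exit node
   of an insertion bubble tends to be adopted *from downstream* (that
   edge is traversed by every carrier) and therefore in reverse
   orientation, which would mistype the bubble's interior edges as
   inversions.
4. Components left unreached (no walks) are anchored to the source
   binode at their smallest node id; their nodes get position −1.

A node's orientation is forward when its parent edge enters it at the
tail, reverse otherwise; reference nodes are forward whenever the
reference walk is written forward. Passing `tie_break_rng` randomises
step (c); the *count* of non-terminal variant edges is invariant to
this choice (property-tested over 100 random graphs), only their
identity changes.

Restrictions in this version: exactly one reference walk per graph, and
it must be a simple path (a reference that revisits nodes is rejected
with an explicit error rather than mis-positioned).

## Genotypes, counts, and missingness

The genotype of a walk is its visit count per variant edge, counted on
the bidirected edge (either traversal direction) — directional counting
would break the basis property for backwards traversals. Per haplotype
(sample, haplotype-index; a haplotype may comprise several contig
walks):

* **CA** = visits of the variant edge; **CR** = visits of the
  *reference edge*, the tree edge (parent(v), v), i.e. the last edge of
  the reference-allele path. Walk boundaries count as traversals of the
  corresponding terminus wiring edges so variants at contig ends are
  counted correctly.
* **GT** = 1 if CA > 0, 0 if CA = 0 and CR > 0. When a haplotype covers
  the locus but follows a third allele (CA = CR = 0), GT is emitted as
  `.` while the zero counts are kept — the 1/0 rules stated above are
  mutually exclusive with this case, which the format cannot otherwise
  express.
* **Missingness**: a haplotype's linear coverage is the union over its
  contigs of [min, max] anchored node positions — a cheap approximation
  that avoids exhaustive traversal. A variant whose position interval
  misses that coverage entirely has CR, CA and GT set to `.`. Variants
  with position −1 use component membership instead. The approximation
  is conservative in the tested direction: a haplotype is never marked
  missing while actually traversing either counted edge
  (property-tested on fragmented simulations).
* Aggregates: RC and AC are sums of the observed CR and CA; AN = RC +
  AC.

`reconstruct_walk` inverts genotyping: the walk with one variant-edge
visit (u, v) follows the unique tree path start → u, the edge, then
v → end; the general case searches visit orders and edge strands,
validating bidirected side-consistency, and raises on infeasible
genotypes or (defensively) if more than one distinct walk passes. The
search is limited to six total visits; multiplicity-aware
reconstruction beyond that is out of scope for this version.

## Superbubbles

The published bubble decompositions come from external toolkits; here
detection is implemented from first principles using the pinch-point
definition. Anchors are reference-path nodes visited exactly once, in
tree orientation, by every walk that spans them (a walk spans a node
when its coverage interval strictly contains the node's coordinates);
as a safety net, an anchor strictly inside any variant edge's position
interval is disqualified. Consecutive anchors bound a superbubble when
at least one variant edge lies between them; a variant edge belongs to
the unique anchor interval containing its position interval, so
non-terminal, positioned variant edges partition across bubbles.
Alleles are the distinct anchor-to-anchor walk subpaths (canonicalised
for traversal direction); interiors are the union of subpath nodes.

Two-variant ("triallelic") bubbles are labelled by, in order: both
endpoints of bubble-subgraph degree three → *properly triallelic*;
exactly one → *overlapping*; one variant edge branching at the entry
and landing on the exit → *nested*; one branching at the entry and the
*other* landing on the exit → *interlocking*. Degree is total edge
degree (tree + variant) within the bubble subgraph. Bubbles whose
entry and exit are tree-adjacent are *insertion* superbubbles; joined
by a variant edge, *deletion* (if both, deletion with a warning);
otherwise neither. Only level-0 bubbles are considered; hierarchical
decomposition is out of scope.

## VCF encoding

One biallelic record per variant edge, sorted by (CHROM, POS), QUAL 60,
FILTER PASS. POS is pos(u) for on-reference indels (whose REF and ALT
get the preceding reference base prepended) and pos(u)+1 otherwise.
When the reference allele is not on the linear reference, REF is `.`,
the allele moves to INFO/NR, and nothing is prepended — so REF always
matches the linear reference when present (asserted for 100 % of
on-reference records in the tests). ID is the oriented node pair
(`>`/`<`). Custom INFO fields: NR, VT, DR (tree-edge distances of u and
v from the reference path — measured in edges, a declared convention),
RC, AC, AN, PV, TR_MOTIF, NIA; per-haplotype columns GT:CR:CA.
Inversions are emitted with REF `.` and symbolic ALT `<INV>`. Variants
with position −1 have no linear coordinate and are held out of the
file. The writer emits text directly because htslib-based writers
refuse REF `.`; files are validated by parsing back with pysam/htslib
in the test suite.

Repeat annotation: an indel is a local tandem repeat with motif s when
its non-empty allele equals s^n and the flanking tree sequence of
length |s| (upstream of the branch point, else downstream of v) equals
s; the minimal period is reported. Nearly-identical alleles (NIA) are
pairs, each ≥ 10 bp, at edit distance exactly 1 (computed with edlib).
The small/large size threshold is 50 bp of combined allele length.

## Graph simplification

For visualisation: variant edges with combined allele length below a
threshold (default 1000 bp; inversions count 0 and are therefore
pruned) are removed; tips — branches off the reference path reduced to
degree ≤ 1, hence in no cycle — are deleted iteratively; maximal
non-branching runs are contracted into single nodes carrying the
concatenated, orientation-respecting sequence (total sequence length is
conserved). The reference walk is never disconnected, and walks are
remapped onto contracted nodes where they survive intact. The output
is ordinary GFA suitable for Bandage.

## Synthetic data

The simulator defines the study conditions for every test. It draws a
uniform-ACGT reference (default 10 kb), plants non-overlapping events —
by default 20 SNPs, 5 small indels (1–10 bp), 2 large deletions
(150–400 bp), 1 inversion (80–200 bp), and 1 insertion (100–160 bp)
carrying a nested SNP — across 4 haplotypes with random carrier sets,
then constructs the graph *exactly*: the reference is split at every
breakpoint, alternative segments are added, haplotype walks route
through their events, and the edge set is precisely the adjacencies the
walks traverse. Optional events: tandem duplications (planted with an
internal breakpoint so the back edge is non-degenerate), interlocking
deletion pairs, large insertions, and fragmentation of haplotypes into
multiple contigs. Everything is deterministic given the seed, and
walk-concatenated sequences are checked against an independent
string-editing oracle.

What this does **not** emulate: alignment/graph-construction artifacts
(minigraph-cactus collapses repeats, producing insertions rather than
duplications), shared coalescent haplotype structure, realistic
mutation-rate spectra, sequencing error, or centromere-scale repeat
tangles. Passing tests therefore demonstrate correctness of the
variant *definition and calling machinery* on exact graphs, not
robustness to construction noise.

## Problem sizes and numerical choices

The test and acceptance workloads use 10 kb (pipeline), 2–6 kb
(round-trip, invariance; 100 graphs × 3 random trees) and ≤ 120 bp
(exhaustive walk enumeration, ≤ 12-node graphs, every walk up to length
12 with each edge used at most twice) references; the whole suite runs
in a few seconds. LCA queries use parent-pointer stepping (graphs here
are small; an Euler-tour index already backs the ancestor tests).
Ties everywhere break deterministically (numeric-aware node id, head
before tail) so repeated runs are byte-identical.

## Known limitations

* One simple reference walk per graph; cyclic or multi-contig linear
  references are rejected rather than approximated.
* Inversion edges carry no alleles or branch points; combined allele
  length 0 is a convention, noted in the VCF header.
* Walk reconstruction is restricted to small, uniquely-ordered
  genotypes.
* A variant edge traversed in both directions by different walks
  yields one variant per surviving direction, with a warning; the
  genotype vector does not distinguish the two strands.
* Superbubble detection relies on linear positions; variant edges in
  unanchored (position −1) components are catalogued but not assigned
  to bubbles.
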