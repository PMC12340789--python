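# treevar

Reference-tree variant definition and cataloguing for bidirected
pangenome graphs.

## The problem

A pangenome reference (such as the HPRC minigraph-cactus graph)
represents each haplotype as a walk through a bidirected sequence
graph. That removes reference bias, but it breaks the classical notion
of a genetic variant: bubble-based definitions produce huge
multiallelic sites in structurally variable regions and cannot express
differences between two sequences that are both absent from the linear
reference (e.g. a SNP inside a polymorphic insertion).

`treevar` implements a variant definition for people who need
well-defined, biallelic, positioned variants from a GFA pangenome: it
builds a **reference tree** T — a bidirected spanning tree containing
every node of the graph G and the full linear-reference walk as a
branch — and catalogues every remaining edge of G as a **variant
edge**. For a variant edge (u, v) with branch point
w = lca_T(u, v):

* reference allele = tree path w → v (excluding w and v),
* alternative allele = tree path w → u (excluding w, including u),
* position = (pos(u), pos(v)) on the linear reference,
* type ∈ {SNP, MNP, insertion, deletion, replacement, duplication,
  inversion},
* genotype of a walk = its visit count per variant edge; with the
  walk's endpoints this identifies the walk uniquely, and the walk can
  be reconstructed from it.

The catalog is written as VCF 4.2 with custom fields (NR, VT, DR, RC,
AC, AN, PV, TR_MOTIF, NIA; per-haplotype GT:CR:CA), including variants
whose reference allele is off the linear reference (REF `.`, allele in
NR). Pinch-point superbubbles are detected and classified
(properly-triallelic / overlapping / nested / interlocking; insertion /
deletion superbubbles), and a simplification pass (prune short variant
edges, trim tips, contract paths) produces Bandage-ready GFA for
complex regions. A built-in simulator generates GFA pangenomes with
planted ground-truth variants for testing.

## Worked example

The toy pangenome from the package fixtures has 11 nodes, a reference
walk 1-2-3-4-5-8-11, and three variant edges.

```bash
python - <<'PY'
import treevar as tv

graph, info = tv.fig1_fixture()          # or tv.read_gfa("graph.gfa", "GRCh38")
tree = tv.build_tree(graph)
variants = tv.call_variants(graph, tree)
green = [w for w in graph.walks if w.sample == "green"][0]
print([v.id_string for v in variants], tv.genotype_walk(green, variants, tree))
genotypes = tv.build_genotypes(graph, tree, variants)
records = tv.make_records(tree, variants, genotypes, chrom="toy")
tv.write_vcf(records, "toy.vcf", tree, chrom="toy")
PY
```

prints

```
['>1>4', '>9>3', '>7>8'] [0, 1, 1]
```

i.e. the "green" haplotype skips the deletion edge (1,4) and carries
the insertion (9,3) and the replacement (7,8) — its genotype over the
three variant edges. The VCF body written above is:

```
toy  1  >1>4  ACGT  A      60  PASS  NR=.;VT=deletion;...;PV=1,6    GT:CR:CA  0:1:0  .:0:0  1:0:1  .:0:0
toy  3  >9>3  G     GACGT  60  PASS  NR=.;VT=insertion;...;PV=3,4   GT:CR:CA  0:1:0  1:0:1  .:0:0  .:0:0
toy  5  >7>8  CTG   GA     60  PASS  NR=.;VT=replacement;...;PV=4,9 GT:CR:CA  0:1:0  1:0:1  0:1:0  .:0:0
```

The deletion is anchored at the base before the deleted sequence
(POS 1, REF `ACGT` → ALT `A`), the insertion likewise (POS 3), and the
replacement sits at POS 5 with REF matching the linear reference
`ACGTCTGATGG` at that coordinate. Sample columns give per-haplotype
GT:CR:CA (reference-edge and variant-edge traversal counts).

The same pipeline is available from the shell:

```bash
treevar simulate --out sim.gfa --truth-out truth.vcf --seed 42
treevar call     --gfa sim.gfa --out calls.vcf
treevar bubbles  --gfa sim.gfa --out bubbles.tsv
treevar simplify --gfa sim.gfa --out simple.gfa --min-allele-len 1000
```

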