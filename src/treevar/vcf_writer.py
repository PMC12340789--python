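"""Extended-VCF serialization of the variant catalog.

The dialect keeps canonical VCF semantics wherever possible and moves
pangenome-specific information into custom fields:

* POS — for indels whose alleles get a prepended base (on-reference
  insertions, deletions and duplications) POS is the position of node
  u, i.e. the base before the allele begins; otherwise POS is one plus
  the position of u.
* REF — must match the linear reference at POS; when the reference
  allele is not on the linear reference, REF is '.' and the
  tree-derived reference allele is stored in INFO/NR instead (with no
  prepended base).
* ID — the variant edge as oriented node ids, '>' forward / '<'
  reverse, as traversed in the graph.
* INFO — NR, VT (variant type), DR (tree-edge distances of u and v
  from the reference path), RC/AC/AN (reference, alternative and total
  traversal counts over all walks), PV (the position pair), TR_MOTIF,
  NIA.
* sample columns — one per haplotype, GT:CR:CA, '.' for missing.

Inversions carry no alleles; they are emitted with REF '.' and the
symbolic ALT <INV>.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import SortOrderError
from .genotyping import GenotypeRecord
from .reference_tree import ReferenceTree
from .variant_catalog import VariantEdge

_INFO_ORDER = ("NR", "VT", "DR", "RC", "AC", "AN", "PV", "TR_MOTIF", "NIA")

HEADER_LINES = [
    '##INFO=<ID=NR,Number=1,Type=String,Description="Non-reference reference '
    'allele: the allele obtained by traversing the reference tree from the '
    'branch point to the end of the variant edge, when that path is off the '
    'linear reference; otherwise \'.\'">',
    '##INFO=<ID=VT,Number=1,Type=String,Description="Variant type: SNP, MNP, '
    'insertion, deletion, replacement, duplication, or inversion">',
    '##INFO=<ID=DR,Number=2,Type=Integer,Description="Distance from reference: '
    'number of reference-tree edges from nodes u and v to their deepest '
    'linear-reference ancestor (-1 when none)">',
    '##INFO=<ID=RC,Number=1,Type=Integer,Description="Total traversals of the '
    'corresponding reference tree edge over all haplotype walks">',
    '##INFO=<ID=AC,Number=1,Type=Integer,Description="Total traversals of the '
    'variant edge over all haplotype walks">',
    '##INFO=<ID=AN,Number=1,Type=Integer,Description="Total traversals of '
    'either the variant edge or the corresponding reference tree edge">',
    '##INFO=<ID=PV,Number=2,Type=Integer,Description="Positions of the variant '
    'edge nodes u and v">',
    '##INFO=<ID=TR_MOTIF,Number=1,Type=String,Description="Repeated motif when '
    'the variant edge is a local tandem repeat, otherwise \'.\'">',
    '##INFO=<ID=NIA,Number=1,Type=String,Description="Nearly identical '
    'alleles: yes when both alleles are >=10 bp and differ by a single base, '
    'else no">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="1 when the haplotype '
    'traverses the variant edge, 0 when it traverses the reference edge '
    'instead, \'.\' when unobserved">',
    '##FORMAT=<ID=CR,Number=1,Type=String,Description="Haplotype traversals '
    'of the reference tree edge">',
    '##FORMAT=<ID=CA,Number=1,Type=String,Description="Haplotype traversals '
    'of the variant edge">',
]


@dataclass
class VcfRecord:
    chrom: str
    pos: int
    id: str
    ref: str
    alt: str
    qual: int = 60
    filter: str = "PASS"
    info: dict = field(default_factory=dict)
    samples: list = field(default_factory=list)  # (gt, cr, ca) str triples

    def to_line(self) -> str:
        info = ";".join(f"{k}={self.info[k]}" for k in _INFO_ORDER if k in self.info)
        fields = [
            self.chrom, str(self.pos), self.id, self.ref, self.alt,
            str(self.qual), self.filter, info,
        ]
        if self.samples:
            fields.append("GT:CR:CA")
            fields.extend(":".join(s) for s in self.samples)
        return "\t".join(fields)


def _fmt(value) -> str:
    return "." if value is None else str(value)


def to_vcf_record(
    variant: VariantEdge,
    genotypes: GenotypeRecord,
    tree: ReferenceTree,
    chrom: str = "ref",
    haplotypes: list | None = None,
) -> VcfRecord:
    """Serialize one variant with its genotype columns."""
    pos_u = variant.pos_pair[0]
    ref_seq = tree.reference_sequence()
    is_indel = variant.vtype in ("insertion", "deletion", "duplication")
    prepend = is_indel and not variant.non_reference and variant.vtype != "inversion"

    if variant.vtype == "inversion":
        pos, ref, alt, nr = pos_u + 1, ".", "<INV>", "."
    elif variant.non_reference:
        pos = pos_u + 1
        ref = "."
        alt = variant.alt_seq or "."
        nr = variant.ref_seq or "."
    elif prepend:
        pos = pos_u
        base = ref_seq[pos - 1]  # the base before the allele begins
        ref = base + variant.ref_seq
        alt = base + variant.alt_seq
        nr = "."
    else:
        pos = pos_u + 1
        ref = variant.ref_seq
        alt = variant.alt_seq
        nr = "."

    info = {
        "NR": nr,
        "VT": variant.vtype,
        "DR": f"{tree.ref_distance[variant.u]},{tree.ref_distance[variant.v]}",
        "RC": genotypes.rc,
        "AC": genotypes.ac,
        "AN": genotypes.an,
        "PV": f"{variant.pos_pair[0]},{variant.pos_pair[1]}",
        "TR_MOTIF": variant.tr_motif or ".",
        "NIA": "yes" if variant.nia else "no",
    }
    if haplotypes is None:
        haplotypes = list(genotypes.per_haplotype)
    samples = []
    for h in haplotypes:
        cr, ca, gt = genotypes.per_haplotype.get(h, (None, None, None))
        samples.append((_fmt(gt), _fmt(cr), _fmt(ca)))
    return VcfRecord(
        chrom=chrom, pos=pos, id=variant.id_string, ref=ref, alt=alt,
        info=info, samples=samples,
    )


def make_records(
    tree: ReferenceTree,
    variants: list,
    genotype_records: list,
    chrom: str = "ref",
) -> list:
    """Sorted VcfRecords for the catalog (unanchored variants with
    position -1 are held back; they have no linear coordinate)."""
    haplotypes = tree.graph.haplotypes()
    records = []
    for variant, gr in zip(variants, genotype_records):
        if variant.pos_pair[0] == -1:
            continue
        records.append(to_vcf_record(variant, gr, tree, chrom, haplotypes))
    records.sort(key=lambda r: (r.chrom, r.pos, r.id))
    return records


def write_vcf(
    records: list,
    path,
    tree: ReferenceTree,
    chrom: str = "ref",
    extra_header: list | None = None,
) -> None:
    """Write records (already sorted by CHROM, POS) as VCF 4.2 text."""
    last = None
    for r in records:
        key = (r.chrom, r.pos)
        if last is not None and key < last:
            raise SortOrderError(
                f"record {r.id} at {key} after {last}; sort by (CHROM, POS)"
            )
        last = key
    haplotypes = tree.graph.haplotypes()
    columns = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if haplotypes:
        columns.append("FORMAT")
        columns.extend(f"{sample}#{hap}" for sample, hap in haplotypes)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={tree.reference_length()}>\n")
        fh.write(
            "##ALT=<ID=INV,Description=\"Inversion edge; joins nodes of "
            "opposite orientation and carries no alleles\">\n"
        )
        for line in HEADER_LINES:
            fh.write(line + "\n")
        for line in extra_header or []:
            fh.write(line + "\n")
        fh.write("\t".join(columns) + "\n")
        for r in records:
            fh.write(r.to_line() + "\n")
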