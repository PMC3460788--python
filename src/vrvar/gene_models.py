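"""Gene models and strand/splice-aware coding-sequence construction.

Genomic coordinates are 1-based inclusive (GFF convention) at the interface;
coding-sequence (CDS) offsets are 0-based half-open internally.  On the minus
strand, CDS offset 0 corresponds to the highest exonic genomic coordinate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

log = logging.getLogger(__name__)

SUBFAMILIES = ("V1R", "V2R", "FPR")

COMPLEMENT = str.maketrans("ACGTacgtN", "TGCAtgcaN")


class InputError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass(frozen=True)
class GeneModel:
    """Genomic structure of one receptor gene (CDS exons only, no UTRs)."""

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]  # 1-based inclusive, sorted by start
    subfamily: str = "V1R"
    clade: str = ""
    cluster_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise InputError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.subfamily not in SUBFAMILIES:
            raise InputError(f"{self.gene_id}: unknown subfamily {self.subfamily!r}")
        exons = tuple(sorted(tuple(e) for e in self.exons))
        for (s, e) in exons:
            if s > e or s < 1:
                raise InputError(f"{self.gene_id}: bad exon ({s},{e})")
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise InputError(f"{self.gene_id}: overlapping exons")
        object.__setattr__(self, "exons", exons)
        if self.cds_length < 3:
            raise InputError(f"{self.gene_id}: coding length < 3")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


@dataclass
class CodingSequence:
    """Spliced CDS of one gene plus its bijective genomic<->CDS position map."""

    gene_id: str
    sequence: str
    genomic_to_cds: dict[int, int]  # 1-based genomic pos -> 0-based CDS offset
    strand: str
    chrom: str
    complete_frame: bool = True
    cds_to_genomic: dict[int, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.cds_to_genomic:
            self.cds_to_genomic = {v: k for k, v in self.genomic_to_cds.items()}

    def __len__(self) -> int:
        return len(self.sequence)


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def build_cds(gene: GeneModel, genome: dict[str, str]) -> CodingSequence:
    """Splice a gene's exons out of the genome into its coding sequence.

    Plus strand: concatenation of exon substrings in genomic order.  Minus
    strand: reverse complement of that concatenation, so the CDS starts at the
    highest genomic exonic coordinate.  A length not divisible by 3 clears
    ``complete_frame`` but is not fatal.
    """
    try:
        chrom_seq = genome[gene.chrom]
    except KeyError:
        raise InputError(f"{gene.gene_id}: chromosome {gene.chrom!r} not in genome")
    forward = []
    positions: list[int] = []
    for start, end in gene.exons:
        if end > len(chrom_seq):
            raise InputError(
                f"{gene.gene_id}: exon ({start},{end}) beyond end of {gene.chrom}"
            )
        forward.append(chrom_seq[start - 1 : end])
        positions.extend(range(start, end + 1))
    spliced = "".join(forward)
    if gene.strand == "+":
        sequence = spliced
        mapping = {pos: i for i, pos in enumerate(positions)}
    else:
        sequence = reverse_complement(spliced)
        n = len(positions)
        mapping = {pos: n - 1 - i for i, pos in enumerate(positions)}
    return CodingSequence(
        gene_id=gene.gene_id,
        sequence=sequence,
        genomic_to_cds=mapping,
        strand=gene.strand,
        chrom=gene.chrom,
        complete_frame=len(sequence) % 3 == 0,
    )


NON_CODING = "non-coding"


def map_variant_to_cds(cds: CodingSequence, pos: int, ref: str, alt: str,
                       chrom: str | None = None):
    """Map a genomic SNP onto CDS coordinates.

    Returns ``(cds_offset, cds_ref, cds_alt)`` with alleles complemented on
    minus-strand genes, or the string ``"non-coding"`` for intronic/flanking
    positions.  A reference-allele mismatch against the spliced sequence is a
    data-integrity error.
    """
    if chrom is not None and chrom != cds.chrom:
        return NON_CODING
    offset = cds.genomic_to_cds.get(pos)
    if offset is None:
        return NON_CODING
    if cds.strand == "-":
        ref = ref.translate(COMPLEMENT)
        alt = alt.translate(COMPLEMENT)
    if cds.sequence[offset] != ref:
        raise InputError(
            f"{cds.gene_id}: reference allele mismatch at {cds.chrom}:{pos} "
            f"(expected {cds.sequence[offset]}, got {ref})"
        )
    return offset, ref, alt


def translate_cds(sequence: str) -> str:
    """Standard-code translation; trailing partial codons are dropped."""
    usable = len(sequence) - len(sequence) % 3
    return str(Seq(sequence[:usable]).translate())


# ---------------------------------------------------------------------------
# reference I/O: genome FASTA + gene models as GFF3 CDS features


def load_gene_models(gff3_path) -> list[GeneModel]:
    """Read gene models from GFF3 CDS features grouped by their gene ID.

    Two models sharing an identical exon set describe the same locus twice;
    the lexicographically first gene_id is kept and the duplicate dropped
    (logged), mirroring reference-set curation of co-located paralogues.
    """
    cols = ["seqid", "source", "type", "start", "end", "score", "strand",
            "phase", "attributes"]
    df = pd.read_csv(gff3_path, sep="\t", comment="#", header=None, names=cols)
    df = df[df["type"] == "CDS"]

    def attr(attrs: str, key: str, default: str = "") -> str:
        for part in attrs.split(";"):
            if "=" in part:
                k, v = part.split("=", 1)
                if k.strip() == key:
                    return v.strip()
        return default

    genes: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        gid = attr(row.attributes, "gene_id") or attr(row.attributes, "ID")
        rec = genes.setdefault(gid, {
            "chrom": row.seqid, "strand": row.strand, "exons": [],
            "subfamily": attr(row.attributes, "subfamily", "V1R"),
            "clade": attr(row.attributes, "clade"),
            "cluster_id": attr(row.attributes, "cluster"),
        })
        rec["exons"].append((int(row.start), int(row.end)))

    seen: dict[tuple, str] = {}
    models = []
    for gid in sorted(genes):
        rec = genes[gid]
        key = (rec["chrom"], rec["strand"], tuple(sorted(rec["exons"])))
        if key in seen:
            log.warning("dropping %s: identical exon set to %s", gid, seen[key])
            continue
        seen[key] = gid
        models.append(GeneModel(
            gene_id=gid, chrom=rec["chrom"], strand=rec["strand"],
            exons=tuple(rec["exons"]), subfamily=rec["subfamily"],
            clade=rec["clade"], cluster_id=rec["cluster_id"],
        ))
    return models


def write_gene_models(models: list[GeneModel], gff3_path) -> None:
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            attrs = (f"ID={g.gene_id};gene_id={g.gene_id};subfamily={g.subfamily};"
                     f"clade={g.clade};cluster={g.cluster_id}")
            for s, e in g.exons:
                fh.write(f"{g.chrom}\tvrvar\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t{attrs}\n")


def load_genome(fasta_path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}


def write_genome(genome: dict[str, str], fasta_path) -> None:
    from Bio.Seq import Seq as _Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO
    records = [SeqRecord(_Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(fasta_path), "fasta")
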