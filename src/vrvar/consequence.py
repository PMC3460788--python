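"""Coding-consequence classification of quality-passing variant calls.

Each SNP in an open reading frame is classed as synonymous, non-synonymous,
stop-gain, stop-loss or ambiguous; indels of 1-50 bp are classed frameshift or
in-frame by length modulo 3.  Stop gains are counted inside the non-synonymous
tally in aggregates (and also reported separately), which keeps per-strain
summary arithmetic self-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from Bio.Data.CodonTable import standard_dna_table

from .gene_models import NON_CODING, CodingSequence, map_variant_to_cds

DEFAULT_QUALITY_THRESHOLD = 10.0

STOP = "*"
_CODON_AA = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_AA[_stop] = STOP


class Category(str, Enum):
    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    STOP_GAIN = "stop_gain"
    STOP_LOSS = "stop_loss"
    AMBIGUOUS = "ambiguous"
    NON_CODING = "non_coding"


class IndelClass(str, Enum):
    FRAMESHIFT = "frameshift"
    INFRAME = "inframe"


@dataclass(frozen=True)
class VariantCall:
    """One called difference from the reference in one strain."""

    chrom: str
    pos: int  # 1-based genomic
    ref_allele: str
    alt_allele: str
    quality: float
    strain: str
    kind: str = "snp"  # 'snp' | 'indel'
    indel_length: int = 0  # signed bp; + insertion, - deletion
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.quality < 0:
            raise ValueError("quality must be >= 0")
        if self.kind == "snp":
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError("SNP alleles must be single bases")
        elif self.kind == "indel":
            if self.indel_length == 0:
                raise ValueError("indel_length must be non-zero for indels")
        else:
            raise ValueError(f"unknown variant kind {self.kind!r}")


@dataclass(frozen=True)
class Consequence:
    category: Category
    codon_index: int = -1
    ref_codon: str = ""
    alt_codon: str = ""
    ref_aa: str = ""
    alt_aa: str = ""


def filter_quality(variants, threshold: float = DEFAULT_QUALITY_THRESHOLD):
    """Keep variants with quality strictly greater than the threshold."""
    return [v for v in variants if v.quality > threshold]


def classify_snp(cds: CodingSequence, variant: VariantCall) -> Consequence:
    """Classify one SNP's effect on the codon it falls in.

    Ambiguous-flagged calls pass through with category ``ambiguous`` (their
    allele identity is not trusted), as do SNPs in genes whose CDS length is
    not a multiple of 3, where no reading frame is defined.
    """
    mapped = map_variant_to_cds(cds, variant.pos, variant.ref_allele,
                                variant.alt_allele, chrom=variant.chrom)
    if mapped == NON_CODING:
        return Consequence(Category.NON_CODING)
    offset, cds_ref, cds_alt = mapped
    if variant.ambiguous or not cds.complete_frame:
        return Consequence(Category.AMBIGUOUS)
    return classify_substitution(cds.sequence, offset, cds_alt)


def classify_substitution(sequence: str, offset: int, alt_base: str) -> Consequence:
    """Classify a single-base substitution at a CDS offset (frame assumed)."""
    if not 0 <= offset < len(sequence):
        raise ValueError(f"CDS offset {offset} outside sequence of length {len(sequence)}")
    codon_index = offset // 3
    within = offset % 3
    ref_codon = sequence[codon_index * 3 : codon_index * 3 + 3]
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    ref_aa = _CODON_AA[ref_codon]
    alt_aa = _CODON_AA[alt_codon]
    if ref_aa != STOP and alt_aa == STOP:
        category = Category.STOP_GAIN
    elif ref_aa == STOP and alt_aa != STOP:
        category = Category.STOP_LOSS
    elif ref_aa == alt_aa:
        category = Category.SYNONYMOUS
    else:
        category = Category.NONSYNONYMOUS
    return Consequence(category, codon_index, ref_codon, alt_codon, ref_aa, alt_aa)


MAX_INDEL_BP = 50


def classify_indel(indel_length: int) -> IndelClass:
    """Frameshift iff |length| mod 3 != 0; 1-50 bp is the calling range."""
    size = abs(indel_length)
    if not 1 <= size <= MAX_INDEL_BP:
        raise ValueError(
            f"indel of {size} bp outside the 1-{MAX_INDEL_BP} bp calling range "
            "(structural-variant territory)"
        )
    return IndelClass.FRAMESHIFT if size % 3 else IndelClass.INFRAME


# categories that count toward the non-synonymous aggregate
NONSYN_CATEGORIES = frozenset({Category.NONSYNONYMOUS, Category.STOP_GAIN,
                               Category.STOP_LOSS})


def annotate_calls(calls, cds_by_gene, gene_of_call,
                   threshold: float = DEFAULT_QUALITY_THRESHOLD):
    """Annotate a list of calls against their genes' coding sequences.

    ``gene_of_call`` maps a call to its gene_id (or None for intergenic).
    Returns a list of (call, gene_id, Consequence-or-IndelClass, cds_offset)
    for quality-passing calls; cds_offset is None for indels and non-coding
    positions.
    """
    out = []
    for call in filter_quality(calls, threshold):
        gid = gene_of_call(call)
        if gid is None:
            continue
        cds = cds_by_gene[gid]
        if call.kind == "indel":
            out.append((call, gid, classify_indel(call.indel_length),
                        cds.genomic_to_cds.get(call.pos)))
        else:
            out.append((call, gid, classify_snp(cds, call),
                        cds.genomic_to_cds.get(call.pos)))
    return out
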