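"""Strain haplotype reconstruction and wild-isolate allele matching.

Each wild-caught isolate contributes two sequenced alleles per gene.  An
isolate matches a strain when at least one allele is exactly identical
(full-CDS string equality, no alignment) to that strain's reconstructed
haplotype.  When several strains match, precedence is: wild-derived strain of
the same subspecies, then laboratory-derived strains, then wild-derived
strains of a different subspecies; ties within a class break
lexicographically by strain name and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

WILD_DERIVED = "wild_derived"
LAB_DERIVED = "lab_derived"

NO_MATCH = "no-match"


@dataclass(frozen=True)
class IsolateAllelePair:
    isolate_id: str
    subspecies: str
    gene_id: str
    allele_1: str
    allele_2: str
    has_indel: bool = False  # flagged only; comparison stays exact equality


@dataclass
class StrainInfo:
    strain: str
    strain_class: str  # wild_derived | lab_derived
    subspecies: str = ""


@dataclass
class StrainCatalog:
    """Reconstructed CDS haplotypes per (gene, strain) plus strain metadata."""

    haplotypes: dict[tuple[str, str], str] = field(default_factory=dict)
    strains: dict[str, StrainInfo] = field(default_factory=dict)

    def add(self, gene_id: str, strain: str, haplotype: str) -> None:
        self.haplotypes[(gene_id, strain)] = haplotype

    def strains_for_gene(self, gene_id: str) -> list[str]:
        return sorted(s for g, s in self.haplotypes if g == gene_id)


class ConflictingAlleleError(ValueError):
    pass


def reconstruct_haplotype(cds_sequence: str, snps) -> str:
    """Substitute each biallelic SNP's alt into the reference CDS.

    ``snps`` is an iterable of (cds_offset, ref, alt).  With no variants the
    haplotype equals the reference.  Two different alt alleles at one offset
    is a conflict (an inbred strain is homozygous)."""
    seq = list(cds_sequence)
    seen: dict[int, str] = {}
    for offset, ref, alt in snps:
        if not 0 <= offset < len(seq):
            raise ValueError(f"SNP offset {offset} outside CDS")
        if offset in seen and seen[offset] != alt:
            raise ConflictingAlleleError(
                f"conflicting alleles at CDS offset {offset}: "
                f"{seen[offset]} vs {alt}"
            )
        if seq[offset] != ref:
            raise ValueError(f"reference mismatch at CDS offset {offset}")
        seen[offset] = alt
        seq[offset] = alt
    return "".join(seq)


def _precedence_rank(info: StrainInfo, isolate_subspecies: str) -> int:
    if info.strain_class == WILD_DERIVED and info.subspecies == isolate_subspecies:
        return 0
    if info.strain_class == LAB_DERIVED:
        return 1
    return 2  # wild-derived, different subspecies


@dataclass(frozen=True)
class MatchResult:
    isolate_id: str
    gene_id: str
    strain: str  # NO_MATCH when neither allele is identical to any haplotype
    matched_class: str = ""
    tied_strains: tuple[str, ...] = ()  # equally preferred alternatives


def match_isolate(pair: IsolateAllelePair, catalog: StrainCatalog) -> MatchResult:
    """Match an isolate's allele pair against the strain haplotype catalog."""
    candidates = []
    for strain in catalog.strains_for_gene(pair.gene_id):
        hap = catalog.haplotypes[(pair.gene_id, strain)]
        for allele in (pair.allele_1, pair.allele_2):
            if len(allele) == len(hap) and allele == hap:
                candidates.append(strain)
                break
    if not candidates:
        return MatchResult(pair.isolate_id, pair.gene_id, NO_MATCH)
    ranked = sorted(candidates, key=lambda s: (
        _precedence_rank(catalog.strains[s], pair.subspecies), s))
    best = ranked[0]
    best_rank = _precedence_rank(catalog.strains[best], pair.subspecies)
    ties = tuple(s for s in ranked[1:]
                 if _precedence_rank(catalog.strains[s], pair.subspecies) == best_rank)
    return MatchResult(pair.isolate_id, pair.gene_id, best,
                       matched_class=catalog.strains[best].strain_class,
                       tied_strains=ties)


def match_matrix(pairs, catalog: StrainCatalog,
                 gene_list: list[str] | None = None):
    """Isolate x gene match table plus per-isolate matched fractions.

    ``gene_list`` is an explicit inclusion list (genes with failed or missing
    sequence are excluded by the caller, never silently dropped here)."""
    if gene_list is not None:
        keep = set(gene_list)
        pairs = [p for p in pairs if p.gene_id in keep]
    results = [match_isolate(p, catalog) for p in pairs]
    table = pd.DataFrame([{
        "isolate_id": r.isolate_id, "gene_id": r.gene_id, "match": r.strain,
        "matched_class": r.matched_class,
        "tied": ",".join(r.tied_strains),
    } for r in results])
    if table.empty:
        return table, pd.DataFrame(columns=["isolate_id", "n_genes", "matched_fraction"])
    summary = (table.assign(matched=table.match != NO_MATCH)
               .groupby("isolate_id")
               .agg(n_genes=("gene_id", "nunique"), matched=("matched", "sum"))
               .reset_index())
    summary["matched_fraction"] = summary.matched / summary.n_genes
    return table, summary


# FASTA interchange: headers follow `isolate|subspecies|gene|allele{1,2}`

def write_isolates_fasta(pairs, path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO
    records = []
    for p in pairs:
        for i, allele in enumerate((p.allele_1, p.allele_2), start=1):
            records.append(SeqRecord(
                Seq(allele), id=f"{p.isolate_id}|{p.subspecies}|{p.gene_id}|allele{i}",
                description=""))
    SeqIO.write(records, str(path), "fasta")


def read_isolates_fasta(path) -> list[IsolateAllelePair]:
    from Bio import SeqIO
    alleles: dict[tuple[str, str, str], dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        isolate, subspecies, gene, which = rec.id.split("|")
        alleles.setdefault((isolate, subspecies, gene), {})[which] = str(rec.seq)
    pairs = []
    for (isolate, subspecies, gene), d in sorted(alleles.items()):
        pairs.append(IsolateAllelePair(isolate, subspecies, gene,
                                       d["allele1"], d["allele2"]))
    return pairs
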