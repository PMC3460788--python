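"""Quality-parsing cascade: from raw per-strain evidence to the analyzable gene set.

A gene is excluded in one strain when (precedence order) it shows a
duplication signature (>50% ambiguous SNP calls), a lineage-specific deletion
(an unresolved run >100 bp where at least one other strain is fully resolved),
or simply incomplete read coverage of the coding region at the mapping-quality
cutoff.  A gene excluded in more than ``max_excluded`` strains for any reason
is then removed from every strain's analyzable set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

DUPLICATION_AMBIGUOUS_FRACTION = 0.5   # strict >
DELETION_MIN_RUN_BP = 100              # strict >
DEFAULT_MAX_EXCLUDED = 3               # "more than three strains"
DEFAULT_MAPQ_THRESHOLD = 30


class Status(str, Enum):
    INCLUDED = "included"
    DUPLICATION = "duplication"
    DELETION = "deletion"
    UNRESOLVED = "unresolved"


@dataclass
class SiteEvidence:
    """Per-base resolvability of one gene's CDS in one strain.

    ``unresolved_intervals`` are 0-based half-open CDS intervals with no read
    above the mapping-quality threshold; empty means fully resolved.
    """

    gene_id: str
    strain: str
    cds_length: int
    unresolved_intervals: list[tuple[int, int]] = field(default_factory=list)
    mapq_threshold: int = DEFAULT_MAPQ_THRESHOLD

    def __post_init__(self) -> None:
        iv = sorted(tuple(i) for i in self.unresolved_intervals)
        for s, e in iv:
            if not (0 <= s < e <= self.cds_length):
                raise ValueError(
                    f"{self.gene_id}/{self.strain}: interval ({s},{e}) outside "
                    f"[0,{self.cds_length})"
                )
        for (_, e1), (s2, _) in zip(iv, iv[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}/{self.strain}: overlapping intervals")
        self.unresolved_intervals = iv

    @property
    def unresolved_bp(self) -> int:
        return sum(e - s for s, e in self.unresolved_intervals)

    def resolved_at(self, start: int, end: int) -> bool:
        """True when no unresolved interval intersects [start, end)."""
        return all(e <= start or s >= end for s, e in self.unresolved_intervals)


@dataclass
class GeneStrainStatus:
    gene_id: str
    strain: str
    status: Status
    reason: str = ""


def assess_coverage(evidence: SiteEvidence) -> str:
    """'complete' iff every CDS base is resolved — a single gap is incomplete."""
    return "complete" if not evidence.unresolved_intervals else "incomplete"


def call_duplication(calls) -> bool:
    """Duplication signature: strictly more than half of a gene x strain's SNP
    calls are ambiguous (two alleles in comparable read proportions in an
    inbred, hence homozygous, genome).  Zero calls is not a duplication."""
    snps = [c for c in calls if c.kind == "snp"]
    if not snps:
        return False
    n_amb = sum(c.ambiguous for c in snps)
    return n_amb / len(snps) > DUPLICATION_AMBIGUOUS_FRACTION


def call_deletion(evidence_by_strain: dict[str, SiteEvidence],
                  min_run_bp: int = DELETION_MIN_RUN_BP) -> set[str]:
    """Strains carrying a lineage-specific deletion of this gene.

    A strain qualifies when it has an unresolved run strictly longer than
    ``min_run_bp`` over an interval at which at least one other strain is
    fully resolved.  A gap shared by every strain is a mapping/homology
    problem, not a deletion.
    """
    deleted = set()
    for strain, ev in evidence_by_strain.items():
        for s, e in ev.unresolved_intervals:
            if e - s <= min_run_bp:
                continue
            if any(other.resolved_at(s, e)
                   for name, other in evidence_by_strain.items() if name != strain):
                deleted.add(strain)
                break
    return deleted


def classify_gene_strain(gene_id: str, strain: str, calls,
                         evidence_by_strain: dict[str, SiteEvidence]) -> GeneStrainStatus:
    """Per-strain verdict with precedence duplication > deletion > unresolved."""
    if call_duplication(calls):
        return GeneStrainStatus(gene_id, strain, Status.DUPLICATION,
                                ">50% ambiguous SNP calls")
    ev = evidence_by_strain[strain]
    if strain in call_deletion(evidence_by_strain):
        return GeneStrainStatus(gene_id, strain, Status.DELETION,
                                f">{DELETION_MIN_RUN_BP} bp lineage-specific coverage gap")
    if assess_coverage(ev) == "incomplete":
        return GeneStrainStatus(gene_id, strain, Status.UNRESOLVED,
                                "incomplete coverage of coding region")
    return GeneStrainStatus(gene_id, strain, Status.INCLUDED)


@dataclass
class ParsedDataset:
    """Outcome of the cascade: final status matrix and per-strain gene sets."""

    statuses: dict[tuple[str, str], GeneStrainStatus]
    strains: list[str]
    genes: list[str]
    aggregate_excluded: set[str]  # genes removed everywhere by the >N-strain rule

    def included(self, gene_id: str, strain: str) -> bool:
        st = self.statuses[(gene_id, strain)]
        return st.status is Status.INCLUDED and gene_id not in self.aggregate_excluded

    def genes_for_strain(self, strain: str) -> list[str]:
        return [g for g in self.genes if self.included(g, strain)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (gene, strain), st in sorted(self.statuses.items()):
            rows.append({
                "gene_id": gene, "strain": strain, "status": st.status.value,
                "reason": st.reason,
                "in_parsed_set": self.included(gene, strain),
            })
        return pd.DataFrame(rows)


def aggregate_exclusions(statuses: dict[tuple[str, str], GeneStrainStatus],
                         max_excluded: int = DEFAULT_MAX_EXCLUDED) -> ParsedDataset:
    """Apply the cross-strain rule: a gene excluded in more than
    ``max_excluded`` strains (for any reason) is dropped from all strains.
    Per-strain reasons are preserved for reporting."""
    genes = sorted({g for g, _ in statuses})
    strains = sorted({s for _, s in statuses})
    removed = set()
    for gene in genes:
        n_excluded = sum(
            statuses[(gene, s)].status is not Status.INCLUDED for s in strains
        )
        if n_excluded > max_excluded:
            removed.add(gene)
    return ParsedDataset(statuses=statuses, strains=strains, genes=genes,
                         aggregate_excluded=removed)


def run_cascade(calls_by_gene_strain, evidence, strains=None,
                max_excluded: int = DEFAULT_MAX_EXCLUDED) -> ParsedDataset:
    """Full cascade over an evidence table.

    ``evidence`` maps (gene_id, strain) -> SiteEvidence and must cover every
    gene x strain cell; ``calls_by_gene_strain`` maps the same keys to lists
    of VariantCall (missing keys mean no calls).
    """
    genes = sorted({g for g, _ in evidence})
    if strains is None:
        strains = sorted({s for _, s in evidence})
    statuses = {}
    for gene in genes:
        ev_by_strain = {s: evidence[(gene, s)] for s in strains}
        for strain in strains:
            calls = calls_by_gene_strain.get((gene, strain), [])
            statuses[(gene, strain)] = classify_gene_strain(
                gene, strain, calls, ev_by_strain)
    return aggregate_exclusions(statuses, max_excluded=max_excluded)
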