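"""Functional-repertoire classification: truncations, frameshifts, and the
one-status-per-gene precedence rule.

Each gene x strain gets exactly one status, assigned in the order
duplication > deletion > truncated > frameshift > intact, both per strain
and when aggregating "affected in at least one strain" across the panel.
Truncation here is an evidence category, not a pseudogene call: a premature
stop near the 3' end, or rescue by alternative splicing, may still yield a
functional receptor.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .consequence import Category, IndelClass
from .repertoire_qc import ParsedDataset, Status

NEAR_3PRIME_FRACTION = 0.95  # stop gains beyond this are flagged, still counted


class FunctionalStatus(str, Enum):
    INTACT = "intact"
    DUPLICATION = "duplication"
    DELETION = "deletion"
    TRUNCATED = "truncated"
    FRAMESHIFT = "frameshift"


# precedence order for both per-strain status and cross-strain aggregation
PRECEDENCE = (FunctionalStatus.DUPLICATION, FunctionalStatus.DELETION,
              FunctionalStatus.TRUNCATED, FunctionalStatus.FRAMESHIFT)


@dataclass(frozen=True)
class TruncationEvent:
    """One premature termination codon introduced by a stop-gain SNP."""

    gene_id: str
    strain: str
    cds_offset: int
    codon_index: int
    relative_position: float  # fraction of CDS length, in [0, 1)
    near_3prime: bool = False
    domain: str = ""


def detect_truncations(annotations: pd.DataFrame,
                       cds_lengths: dict[str, int]) -> list[TruncationEvent]:
    """One event per stop-gain SNP; a gene may carry several (stop losses are
    never truncations and are left to the annotation table)."""
    events = []
    stops = annotations[annotations.category == Category.STOP_GAIN.value]
    for row in stops.itertuples(index=False):
        length = cds_lengths[row.gene_id]
        rel = row.cds_offset / length
        events.append(TruncationEvent(
            gene_id=row.gene_id, strain=row.strain, cds_offset=int(row.cds_offset),
            codon_index=int(row.cds_offset) // 3, relative_position=rel,
            near_3prime=rel >= NEAR_3PRIME_FRACTION,
        ))
    return events


def detect_frameshifts(annotated_indels) -> set[tuple[str, str]]:
    """(gene, strain) pairs with at least one frameshift indel.

    Compensatory indel pairs are not modeled: any frameshift-length indel is
    frameshift evidence."""
    return {(gid, call.strain) for call, gid, cls, _ in annotated_indels
            if call.kind == "indel" and cls is IndelClass.FRAMESHIFT}


_QC_TO_FUNCTIONAL = {Status.DUPLICATION: FunctionalStatus.DUPLICATION,
                     Status.DELETION: FunctionalStatus.DELETION}


def assign_status(gene_id: str, strain: str, qc_status: Status,
                  truncated: bool, frameshifted: bool) -> FunctionalStatus:
    """First matching category in precedence order, else intact."""
    if qc_status in _QC_TO_FUNCTIONAL:
        return _QC_TO_FUNCTIONAL[qc_status]
    if truncated:
        return FunctionalStatus.TRUNCATED
    if frameshifted:
        return FunctionalStatus.FRAMESHIFT
    return FunctionalStatus.INTACT


def status_table(parsed: ParsedDataset, truncations, frameshift_pairs) -> pd.DataFrame:
    """Per gene x strain functional status over the parsed dataset.

    Genes dropped everywhere by the aggregation rule are omitted; genes
    unresolved in one strain but retained in the parsed set keep their
    event-based status there only if events exist (unresolved cells stay
    intact-by-absence-of-evidence and are marked)."""
    trunc_pairs = {(e.gene_id, e.strain) for e in truncations}
    rows = []
    for gene in parsed.genes:
        if gene in parsed.aggregate_excluded:
            continue
        for strain in parsed.strains:
            qc = parsed.statuses[(gene, strain)].status
            st = assign_status(gene, strain, qc,
                               (gene, strain) in trunc_pairs,
                               (gene, strain) in frameshift_pairs)
            rows.append({"gene_id": gene, "strain": strain,
                         "status": st.value, "qc_status": qc.value})
    return pd.DataFrame(rows)


def aggregate_repertoire(statuses: pd.DataFrame) -> pd.DataFrame:
    """Cross-strain proportions: each gene counted once, in precedence order,
    under the highest-precedence status it shows in any strain.

    Returns one row per status with counts and percentages of the gene
    denominator (genes present in the status table)."""
    genes = sorted(statuses.gene_id.unique())
    per_gene = {}
    by_gene = statuses.groupby("gene_id")["status"].agg(set)
    for gene in genes:
        seen = by_gene[gene]
        for status in PRECEDENCE:
            if status.value in seen:
                per_gene[gene] = status
                break
        else:
            per_gene[gene] = FunctionalStatus.INTACT
    n = len(genes)
    rows = []
    for status in (*PRECEDENCE, FunctionalStatus.INTACT):
        count = sum(1 for s in per_gene.values() if s is status)
        rows.append({"status": status.value, "n_genes": count,
                     "pct_of_analysed": round(100.0 * count / n, 1) if n else 0.0})
    return pd.DataFrame(rows)


def per_strain_counts(statuses: pd.DataFrame) -> pd.DataFrame:
    """Status counts per strain; rows sum to the parsed gene count."""
    return (statuses.groupby(["strain", "status"]).size()
            .unstack(fill_value=0).reset_index())
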