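"""Partition V2R coding sequences at the first trans-membrane boundary.

V2Rs carry a long extracellular N-terminal domain implicated in ligand
recognition ahead of the conserved seven-trans-membrane region.  The split is
binary at the supplied boundary offset: N-terminal = [0, tm_start),
trans-membrane-and-beyond = [tm_start, |CDS|), assigned by the nucleotide
offset of each variant site (half-open, so a SNP exactly at the boundary
falls on the trans-membrane side).  Short inter-helix loops need no special
treatment under a binary split.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .consequence import NONSYN_CATEGORIES, Category

N_TERMINAL = "N-terminal"
TRANSMEMBRANE = "transmembrane"
UNANNOTATED = "unannotated"


@dataclass(frozen=True)
class DomainAnnotation:
    """CDS offset of the first base of the first trans-membrane domain."""

    gene_id: str
    tm_start: int

    def validate(self, cds_length: int) -> None:
        if not 0 < self.tm_start < cds_length:
            raise ValueError(
                f"{self.gene_id}: tm_start {self.tm_start} outside (0, {cds_length})"
            )


def load_domain_annotations(tsv_path) -> dict[str, DomainAnnotation]:
    df = pd.read_csv(tsv_path, sep="\t")
    return {r.gene_id: DomainAnnotation(r.gene_id, int(r.tm_start))
            for r in df.itertuples(index=False)}


def domain_of(offset: int, tm_start: int) -> str:
    return N_TERMINAL if offset < tm_start else TRANSMEMBRANE


def domain_rates(cds_length: int, annotation: DomainAnnotation,
                 gene_annotations: pd.DataFrame) -> pd.DataFrame:
    """Per-domain synonymous/non-synonymous densities for one gene.

    Counts the gene's SNP annotations on each side of the boundary and
    normalises by domain length in kb; the non-syn:syn ratio is NaN where a
    domain has no synonymous SNPs.
    """
    annotation.validate(cds_length)
    nonsyn_vals = [c.value for c in NONSYN_CATEGORIES]
    rows = []
    bounds = {N_TERMINAL: (0, annotation.tm_start),
              TRANSMEMBRANE: (annotation.tm_start, cds_length)}
    for domain, (lo, hi) in bounds.items():
        sub = gene_annotations[(gene_annotations.cds_offset >= lo)
                               & (gene_annotations.cds_offset < hi)]
        kb = (hi - lo) / 1000.0
        n_syn = int((sub.category == Category.SYNONYMOUS.value).sum())
        n_nonsyn = int(sub.category.isin(nonsyn_vals).sum())
        rows.append({
            "gene_id": annotation.gene_id, "domain": domain,
            "length_bp": hi - lo,
            "syn_per_kb": n_syn / kb, "nonsyn_per_kb": n_nonsyn / kb,
            "n_syn": n_syn, "n_nonsyn": n_nonsyn,
            "nonsyn_syn_ratio": (n_nonsyn / n_syn) if n_syn else float("nan"),
        })
    return pd.DataFrame(rows)


def pooled_domain_rates(cds_lengths: dict[str, int],
                        annotations_by_gene: dict[str, DomainAnnotation],
                        snp_annotations: pd.DataFrame,
                        strains: list[str] | None = None) -> pd.DataFrame:
    """Pooled per-domain counts and densities over a set of V2R genes."""
    ann = snp_annotations
    if strains is not None:
        ann = ann[ann.strain.isin(strains)]
    frames = []
    for gid, dom in annotations_by_gene.items():
        frames.append(domain_rates(cds_lengths[gid], dom,
                                   ann[ann.gene_id == gid]))
    per_gene = pd.concat(frames, ignore_index=True)
    pooled = per_gene.groupby("domain").agg(
        length_bp=("length_bp", "sum"), n_syn=("n_syn", "sum"),
        n_nonsyn=("n_nonsyn", "sum")).reset_index()
    pooled["syn_per_kb"] = 1000.0 * pooled.n_syn / pooled.length_bp
    pooled["nonsyn_per_kb"] = 1000.0 * pooled.n_nonsyn / pooled.length_bp
    return pooled


def stop_positions_by_domain(truncations,
                             annotations_by_gene: dict[str, DomainAnnotation]):
    """Label each truncation event N-terminal / trans-membrane by its offset;
    events in genes without a boundary annotation are labeled, never dropped."""
    labeled = []
    for event in truncations:
        dom = annotations_by_gene.get(event.gene_id)
        label = UNANNOTATED if dom is None else domain_of(event.cds_offset, dom.tm_start)
        labeled.append((event, label))
    return labeled
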