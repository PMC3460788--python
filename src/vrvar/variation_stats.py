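"""Per-strain and pooled SNP summary statistics.

Counts are computed over the parsed (post-cascade) gene set per strain.
The non-synonymous tally includes stop gains, which are also reported
separately as truncating SNPs; a private SNP is a (gene, CDS site, alt
allele) observed in exactly one strain among the strains in which that gene
survived parsing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consequence import NONSYN_CATEGORIES, Category


@dataclass
class StrainSummary:
    """One strain's row of the repertoire summary table."""

    strain: str
    n_genes_parsed: int = 0
    resolved_bp: int = 0
    unresolved_bp: int = 0
    n_snps: int = 0
    n_nonsyn: int = 0
    n_private: int = 0
    n_truncating: int = 0
    has_snps: bool = True  # False flags undefined percentages (zero SNPs)

    @property
    def pct_unresolved(self) -> float:
        total = self.resolved_bp + self.unresolved_bp
        return 100.0 * self.unresolved_bp / total if total else 0.0

    @property
    def pct_nonsyn(self) -> float:
        return 100.0 * self.n_nonsyn / self.n_snps if self.n_snps else 0.0

    @property
    def pct_private(self) -> float:
        return 100.0 * self.n_private / self.n_snps if self.n_snps else 0.0

    @property
    def pct_truncating(self) -> float:
        return 100.0 * self.n_truncating / self.n_snps if self.n_snps else 0.0


def percentage(count: int, denominator: int, decimals: int = 1) -> float:
    """Rounded percentage as printed in summary tables (one decimal place)."""
    if denominator == 0:
        return 0.0
    return round(100.0 * count / denominator, decimals)


# annotations: DataFrame with columns
#   gene_id, strain, pos, cds_offset, alt, category (Category values as str)
ANNOT_COLUMNS = ["gene_id", "strain", "pos", "cds_offset", "ref", "alt", "category"]


def annotations_frame(annotated) -> pd.DataFrame:
    """Tabulate annotated SNP calls from the consequence module."""
    rows = []
    for call, gid, cons, cds_offset in annotated:
        if call.kind != "snp":
            continue
        rows.append({
            "gene_id": gid, "strain": call.strain, "pos": call.pos,
            "cds_offset": -1 if cds_offset is None else cds_offset,
            "ref": call.ref_allele, "alt": call.alt_allele,
            "category": cons.category.value,
        })
    return pd.DataFrame(rows, columns=ANNOT_COLUMNS)


def find_private_snps(annotations: pd.DataFrame, parsed) -> dict[str, pd.DataFrame]:
    """Per-strain private SNP sets.

    A SNP keyed by (gene, genomic position, alt allele) is private to strain s
    iff it occurs in s and in no other strain in which the gene is in the
    parsed set.  The returned per-strain frames are pairwise disjoint.
    """
    ann = annotations[[
        parsed.included(g, s) for g, s in zip(annotations.gene_id, annotations.strain)
    ]]
    if ann.empty:
        return {s: ann for s in parsed.strains}
    counts = ann.groupby(["gene_id", "pos", "alt"])["strain"].nunique()
    singleton = counts[counts == 1].index
    keyed = ann.set_index(["gene_id", "pos", "alt"])
    private = keyed.loc[keyed.index.isin(singleton)].reset_index()
    return {s: grp for s, grp in private.groupby("strain")} | {
        s: private.iloc[0:0] for s in parsed.strains
        if s not in set(private.strain)
    }


def summarize_strain(parsed, annotations: pd.DataFrame, evidence,
                     cds_lengths: dict[str, int], strain: str,
                     private: dict[str, pd.DataFrame] | None = None) -> StrainSummary:
    """Assemble one strain's summary row from the parsed dataset.

    ``evidence`` maps (gene_id, strain) -> SiteEvidence; resolved bp sums
    |CDS| - unresolved bases over included genes, while the unresolved
    percentage is taken against the pre-parsing total coding length.
    """
    if strain not in parsed.strains:
        raise ValueError(f"unknown strain {strain!r}")
    genes = parsed.genes_for_strain(strain)
    gene_set = set(genes)
    resolved = sum(cds_lengths[g] - evidence[(g, strain)].unresolved_bp for g in genes)
    total_bp = sum(cds_lengths[g] for g in parsed.genes)

    ann = annotations[(annotations.strain == strain)
                      & annotations.gene_id.isin(gene_set)]
    n_snps = len(ann)
    n_nonsyn = int(ann.category.isin([c.value for c in NONSYN_CATEGORIES]).sum())
    n_trunc = int((ann.category == Category.STOP_GAIN.value).sum())
    if private is None:
        private = find_private_snps(annotations, parsed)
    n_private = len(private.get(strain, ()))
    return StrainSummary(
        strain=strain, n_genes_parsed=len(genes), resolved_bp=resolved,
        unresolved_bp=total_bp - resolved, n_snps=n_snps, n_nonsyn=n_nonsyn,
        n_private=n_private, n_truncating=n_trunc, has_snps=n_snps > 0,
    )


def summary_table(parsed, annotations, evidence, cds_lengths) -> pd.DataFrame:
    private = find_private_snps(annotations, parsed)
    rows = []
    for strain in parsed.strains:
        s = summarize_strain(parsed, annotations, evidence, cds_lengths, strain,
                             private=private)
        rows.append({
            "strain": s.strain, "vrs_after_parsing": s.n_genes_parsed,
            "resolved_kb": round(s.resolved_bp / 1000, 3),
            "unresolved_pct": round(s.pct_unresolved, 1),
            "all_snps": s.n_snps, "nonsyn_snps": s.n_nonsyn,
            "nonsyn_pct": round(s.pct_nonsyn, 1),
            "private_snps": s.n_private, "private_pct": round(s.pct_private, 1),
            "truncating": s.n_truncating,
            "truncating_pct": round(s.pct_truncating, 2),
        })
    return pd.DataFrame(rows)


def codons_per_snp(total_coding_bp: int, snp_count: int) -> int:
    """Average codon spacing between SNPs over a coding-bp total.

    E.g. one non-synonymous SNP every 273 codons of receptor coding sequence.
    Returns the nearest integer; zero SNPs leaves the density undefined.
    """
    if snp_count <= 0:
        raise ZeroDivisionError("no density defined for zero SNPs")
    return round((total_coding_bp / 3) / snp_count)


def nonsyn_syn_ratio(n_nonsyn: int, n_syn: int) -> float:
    """Non-synonymous : synonymous SNP count ratio (2-decimal reporting)."""
    if n_syn == 0:
        raise ZeroDivisionError("ratio undefined with zero synonymous SNPs")
    return round(n_nonsyn / n_syn, 2)


MISSING_DUPLICATION = "duplication"
MISSING_DELETION = "deletion"
MISSING_UNRESOLVED = "unresolved"


@dataclass
class DensityMatrix:
    """Gene x strain non-synonymous SNPs per kb, with exclusion markers.

    ``values`` holds NaN where a cell is excluded; ``markers`` carries the
    exclusion reason so renderers can distinguish duplication/deletion cells
    from genuinely variant-free (0.0) cells.
    """

    values: pd.DataFrame
    markers: pd.DataFrame = field(repr=False, default=None)


def density_matrix(parsed, annotations: pd.DataFrame,
                   cds_lengths: dict[str, int], gene_order: list[str]) -> DensityMatrix:
    """1000 x non-syn count / |CDS| for each included gene x strain cell.

    Row order follows ``gene_order`` (a phylogeny ordering supplied by the
    caller); excluded cells are NaN with a reason marker.
    """
    unknown = [g for g in gene_order if g not in set(parsed.genes)]
    if unknown:
        raise ValueError(f"genes in ordering but not in dataset: {unknown}")
    nonsyn = annotations[annotations.category.isin(
        [c.value for c in NONSYN_CATEGORIES])]
    counts = nonsyn.groupby(["gene_id", "strain"]).size()
    values = pd.DataFrame(index=gene_order, columns=parsed.strains, dtype=float)
    markers = pd.DataFrame("", index=gene_order, columns=parsed.strains)
    for gene in gene_order:
        for strain in parsed.strains:
            if parsed.included(gene, strain):
                n = counts.get((gene, strain), 0)
                values.loc[gene, strain] = 1000.0 * n / cds_lengths[gene]
            else:
                values.loc[gene, strain] = np.nan
                markers.loc[gene, strain] = parsed.statuses[(gene, strain)].status.value
    return DensityMatrix(values=values, markers=markers)


def subfamily_density(parsed, annotations: pd.DataFrame, evidence,
                      cds_lengths: dict[str, int],
                      subfamily_of: dict[str, str],
                      strain_pools: dict[str, list[str]]) -> pd.DataFrame:
    """Mean non-synonymous SNPs per resolved kb, by strain pool x subfamily.

    Per strain, density = non-syn SNPs in the subfamily's included genes /
    resolved subfamily kb; the pool value is the mean over its strains with
    the standard error of that mean.
    """
    nonsyn = annotations[annotations.category.isin(
        [c.value for c in NONSYN_CATEGORIES])]
    rows = []
    for pool, strains in strain_pools.items():
        for subfam in sorted(set(subfamily_of.values())):
            densities = []
            for strain in strains:
                genes = [g for g in parsed.genes_for_strain(strain)
                         if subfamily_of[g] == subfam]
                kb = sum(cds_lengths[g] - evidence[(g, strain)].unresolved_bp
                         for g in genes) / 1000.0
                if kb == 0:
                    continue
                n = len(nonsyn[(nonsyn.strain == strain)
                               & nonsyn.gene_id.isin(set(genes))])
                densities.append(n / kb)
            if not densities:
                rows.append({"pool": pool, "subfamily": subfam,
                             "mean_nonsyn_per_kb": np.nan, "sem": np.nan,
                             "n_strains": 0, "empty": True})
                continue
            arr = np.asarray(densities)
            sem = arr.std(ddof=1) / np.sqrt(len(arr)) if len(arr) > 1 else 0.0
            rows.append({"pool": pool, "subfamily": subfam,
                         "mean_nonsyn_per_kb": arr.mean(), "sem": sem,
                         "n_strains": len(arr), "empty": False})
    return pd.DataFrame(rows)
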