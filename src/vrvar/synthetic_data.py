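"""Synthetic receptor repertoires with a planted-truth ledger.

Generates the three layers of input the analysis consumes, emulating the
structure of the real study inputs so every downstream stage is testable
without external data:

* a reference "genome" of receptor genes arranged in tightly clustered,
  highly homologous arrays on both strands (single-exon V1R/FPR-like genes,
  multi-exon V2R-like genes);
* per-strain variant calls and per-base resolvability evidence for a panel
  of inbred strains, organised in groups — laboratory-derived strains share
  most of their variants, wild-derived strains are divergent and mostly
  group-specific — with planted synonymous/non-synonymous/stop-gain SNPs,
  1-50 bp indels, >100 bp lineage-specific coverage-gap deletions and
  duplication signatures (co-segregating ambiguous calls);
* wild-isolate allele pairs drawn from strain haplotypes plus novel alleles.

Every planted event is recorded in a truth ledger keyed by (gene, strain) so
recovery can be scored exactly.  All randomness flows from one seed through
named substreams; identical config + seed reproduces identical output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .consequence import Category, VariantCall, classify_substitution
from .gene_models import CodingSequence, GeneModel, build_cds, reverse_complement
from .haplotype_match import (LAB_DERIVED, WILD_DERIVED, StrainCatalog,
                              StrainInfo, IsolateAllelePair,
                              reconstruct_haplotype)
from .repertoire_qc import SiteEvidence


class ConfigurationError(ValueError):
    pass


BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")
_ALL_CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
SENSE_CODONS = [c for c in _ALL_CODONS if c not in STOP_CODONS]


@dataclass(frozen=True)
class StrainGroup:
    """One group of strains sharing ancestry (and therefore SNPs)."""

    name: str
    n_strains: int
    snp_rate_per_kb: float  # expected quality-passing SNPs per strain per kb
    shared_fraction: float  # fraction of a strain's SNPs shared group-wide
    strain_class: str = LAB_DERIVED
    subspecies: str = "domesticus"

    def strain_names(self) -> list[str]:
        if self.n_strains == 1:
            return [self.name]
        return [f"{self.name}_{i + 1:02d}" for i in range(self.n_strains)]


# Default panel mirrors the study: 13 laboratory-derived strains (largely
# M. m. domesticus in origin, sharing most variants) and four wild-derived
# strains of increasing divergence from the reference.  Per-kb SNP rates are
# the study's per-strain SNP counts over resolved coding kb.
DEFAULT_STRAIN_GROUPS = (
    StrainGroup("lab", 13, 1.1, 0.8, LAB_DERIVED, "domesticus"),
    StrainGroup("wild_domesticus", 1, 1.5, 0.0, WILD_DERIVED, "domesticus"),
    StrainGroup("wild_musculus", 1, 4.7, 0.0, WILD_DERIVED, "musculus"),
    StrainGroup("wild_castaneus", 1, 5.0, 0.0, WILD_DERIVED, "castaneus"),
    StrainGroup("wild_spretus", 1, 13.2, 0.0, WILD_DERIVED, "spretus"),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; defaults emulate the study's conditions
    (366 reference receptor genes in clusters, 17 strains in five groups)."""

    n_clusters: int = 92
    genes_per_cluster: int = 4
    within_cluster_identity: float = 0.95
    n_exons_range: tuple[int, int] = (1, 6)
    strand_fraction_minus: float = 0.5
    strain_groups: tuple[StrainGroup, ...] = DEFAULT_STRAIN_GROUPS
    stop_gain_rate: float = 0.05       # per-gene probability of a planted stop
    indel_rate: float = 0.05           # per-gene probability of a 1-50 bp indel
    deletion_rate: float = 0.05        # per-gene probability of a >100 bp deletion
    duplication_rate: float = 0.05     # per-gene probability of a duplication signature
    unresolvable_rate: float = 0.03    # per-gene probability of panel-wide mapping failure
    low_quality_rate_per_kb: float = 0.1  # noise calls below the quality cutoff
    fraction_v2r: float = 0.33
    fraction_fpr: float = 0.02
    seed: int = 0

    @property
    def n_genes(self) -> int:
        return self.n_clusters * self.genes_per_cluster

    def validate(self) -> None:
        fractions = {
            "within_cluster_identity": self.within_cluster_identity,
            "strand_fraction_minus": self.strand_fraction_minus,
            "fraction_v2r": self.fraction_v2r, "fraction_fpr": self.fraction_fpr,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {value}")
        for name in ("stop_gain_rate", "indel_rate", "deletion_rate",
                     "duplication_rate", "unresolvable_rate",
                     "low_quality_rate_per_kb"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.within_cluster_identity >= 1.0 and self.genes_per_cluster > 1:
            raise ConfigurationError(
                "within_cluster_identity 1.0 is impossible: cluster members "
                "must carry distinguishing variation")
        lo, hi = self.n_exons_range
        if not 1 <= lo <= hi:
            raise ConfigurationError("n_exons_range must satisfy 1 <= lo <= hi")
        for g in self.strain_groups:
            if not 0.0 <= g.shared_fraction <= 1.0:
                raise ConfigurationError(f"{g.name}: shared_fraction outside [0,1]")
            if g.snp_rate_per_kb < 0:
                raise ConfigurationError(f"{g.name}: negative SNP rate")

    def strains(self) -> list[str]:
        return [s for g in self.strain_groups for s in g.strain_names()]

    def strain_catalog_info(self) -> dict[str, StrainInfo]:
        return {s: StrainInfo(s, g.strain_class, g.subspecies)
                for g in self.strain_groups for s in g.strain_names()}


EVENT_KINDS = ("syn_snp", "nonsyn_snp", "stop_gain", "frameshift_indel",
               "inframe_indel", "deletion", "duplication")

LEDGER_COLUMNS = ["gene_id", "strain", "kind", "cds_start", "cds_end",
                  "ref", "alt", "ambiguous", "passes_quality"]


@dataclass
class TruthLedger:
    """Planted-event record, one row per event per (gene, strain)."""

    events: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=LEDGER_COLUMNS))

    def of_kind(self, *kinds: str) -> pd.DataFrame:
        return self.events[self.events.kind.isin(kinds)]

    def pairs_of_kind(self, *kinds: str) -> set[tuple[str, str]]:
        sub = self.of_kind(*kinds)
        return set(zip(sub.gene_id, sub.strain))

    def call_count(self, gene_id: str, strain: str) -> int:
        sub = self.events
        return int(((sub.gene_id == gene_id) & (sub.strain == strain)
                    & sub.kind.isin(["syn_snp", "nonsyn_snp", "stop_gain",
                                     "frameshift_indel", "inframe_indel"])).sum())

    def write(self, path) -> None:
        self.events.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "TruthLedger":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class ReferenceBundle:
    genome: dict[str, str]
    genes: list[GeneModel]
    cds: dict[str, CodingSequence]
    domain_annotations: dict[str, int]  # V2R gene_id -> tm_start CDS offset

    def cds_lengths(self) -> dict[str, int]:
        return {g: len(c) for g, c in self.cds.items()}


# ---------------------------------------------------------------------------
# reference generation


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    middle = rng.choice(SENSE_CODONS, size=n_codons - 2)
    stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
    return "ATG" + "".join(middle) + stop


def _mutate_codons(rng: np.random.Generator, cds: str,
                   codon_indices: np.ndarray) -> str:
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    for ci in codon_indices:
        choices = [c for c in SENSE_CODONS if c != codons[ci]]
        codons[ci] = choices[rng.integers(len(choices))]
    return "".join(codons)


def _split_lengths(rng: np.random.Generator, total: int, parts: int,
                   minimum: int = 30) -> list[int]:
    if parts == 1:
        return [total]
    # random composition with a per-part floor
    free = total - minimum * parts
    cuts = np.sort(rng.integers(0, free + 1, size=parts - 1))
    sizes = np.diff(np.concatenate([[0], cuts, [free]]))
    return [minimum + int(s) for s in sizes]


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.asarray(list(BASES))[rng.integers(0, 4, size=n)])


def generate_reference(config: SimulationConfig) -> ReferenceBundle:
    """Build the clustered reference gene set, one chromosome per cluster.

    Cluster members derive from a common ancestral CDS by replacing disjoint
    sets of codons, which bounds every within-cluster pairwise identity at or
    above ``within_cluster_identity``.  V2R-like clusters are multi-exonic;
    V1R/FPR-like clusters are single-exon.  Strand drawn per gene.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    domains: dict[str, int] = {}

    n_v2r = round(config.n_clusters * config.fraction_v2r)
    n_fpr = round(config.n_clusters * config.fraction_fpr)
    subfams = (["V2R"] * n_v2r + ["FPR"] * n_fpr
               + ["V1R"] * (config.n_clusters - n_v2r - n_fpr))
    rng.shuffle(subfams)

    codon_ranges = {"V1R": (280, 321), "V2R": (800, 901), "FPR": (330, 361)}
    lo_ex, hi_ex = config.n_exons_range

    for ci in range(config.n_clusters):
        subfam = subfams[ci]
        chrom = f"chr{ci + 1}"
        cluster_id = f"cluster{ci + 1:03d}"
        clade = f"{subfam}-{chr(ord('A') + ci % 8)}"
        n_codons = int(rng.integers(*codon_ranges[subfam]))
        ancestor = _random_cds(rng, n_codons)
        L = len(ancestor)

        # disjoint codon sets; up to 3 nt changes per mutated codon on each
        # of two genes bounds pairwise difference by 6k
        k = int((1.0 - config.within_cluster_identity) * L // 6)
        mutable = np.arange(1, n_codons - 1)
        needed = k * config.genes_per_cluster
        if needed > len(mutable):
            raise ConfigurationError(
                f"cluster of {config.genes_per_cluster} genes cannot hold "
                f"{needed} disjoint mutated codons in {len(mutable)} positions")
        chosen = rng.choice(mutable, size=needed, replace=False) if needed else np.array([], int)

        chrom_parts: list[str] = []
        cursor = 0
        for gi in range(config.genes_per_cluster):
            gene_id = f"{subfam.lower()}_{ci + 1:03d}_{gi + 1}"
            own = chosen[gi * k:(gi + 1) * k]
            cds_seq = _mutate_codons(rng, ancestor, own) if k else ancestor

            if subfam == "V2R" and hi_ex >= 2:
                n_exons = int(rng.integers(max(2, lo_ex), hi_ex + 1))
            else:
                n_exons = 1
            exon_lengths = _split_lengths(rng, L, n_exons)
            strand = "-" if rng.random() < config.strand_fraction_minus else "+"
            genomic_cds = cds_seq if strand == "+" else reverse_complement(cds_seq)
            if strand == "-":
                exon_lengths = exon_lengths[::-1]

            spacer = _random_dna(rng, int(rng.integers(300, 601)))
            chrom_parts.append(spacer)
            cursor += len(spacer)
            exons = []
            offset = 0
            for ei, elen in enumerate(exon_lengths):
                if ei:
                    intron = _random_dna(rng, int(rng.integers(100, 301)))
                    chrom_parts.append(intron)
                    cursor += len(intron)
                chrom_parts.append(genomic_cds[offset:offset + elen])
                exons.append((cursor + 1, cursor + elen))  # 1-based inclusive
                cursor += elen
                offset += elen
            genes.append(GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                                   exons=tuple(exons), subfamily=subfam,
                                   clade=clade, cluster_id=cluster_id))
            if subfam == "V2R":
                # extracellular N-terminus is roughly the first 70% of the CDS
                tm = int(0.7 * (L // 3)) * 3
                domains[gene_id] = tm
        chrom_parts.append(_random_dna(rng, int(rng.integers(300, 601))))
        genome[chrom] = "".join(chrom_parts)

    cds = {g.gene_id: build_cds(g, genome) for g in genes}
    return ReferenceBundle(genome=genome, genes=genes, cds=cds,
                           domain_annotations=domains)


# ---------------------------------------------------------------------------
# strain simulation


def _stop_gain_candidates(cds_seq: str) -> list[tuple[int, str]]:
    """(offset, alt) pairs whose substitution creates a premature stop."""
    out = []
    n_codons = len(cds_seq) // 3
    for ci in range(1, n_codons - 1):
        codon = cds_seq[ci * 3:ci * 3 + 3]
        for within in range(3):
            for alt in BASES:
                if alt == codon[within]:
                    continue
                mutated = codon[:within] + alt + codon[within + 1:]
                if mutated in STOP_CODONS:
                    out.append((ci * 3 + within, alt))
    return out


def _in_intervals(offset: int, intervals) -> bool:
    return any(s <= offset < e for s, e in intervals)


class _GeneSim:
    """Accumulates planted events for one gene, avoiding site collisions."""

    def __init__(self, cds: CodingSequence, rng: np.random.Generator):
        self.cds = cds
        self.rng = rng
        self.used_offsets: set[int] = set()
        self.L = len(cds)

    def draw_offset(self, forbidden_intervals=()) -> int | None:
        for _ in range(200):
            off = int(self.rng.integers(3, self.L - 3))  # keep start/stop codons
            if off in self.used_offsets or _in_intervals(off, forbidden_intervals):
                continue
            self.used_offsets.add(off)
            return off
        return None

    def draw_snp(self, allow_stop: bool = False):
        """(offset, ref, alt, kind) for a substitution; redraws alleles that
        would create a stop unless asked for one (stops are planted
        separately so recovery is exactly scoreable)."""
        off = self.draw_offset()
        if off is None:
            return None
        ref = self.cds.sequence[off]
        for _ in range(50):
            alt = BASES[self.rng.integers(4)]
            if alt == ref:
                continue
            cons = classify_substitution(self.cds.sequence, off, alt)
            if cons.category is Category.STOP_GAIN and not allow_stop:
                continue
            kind = {Category.SYNONYMOUS: "syn_snp",
                    Category.NONSYNONYMOUS: "nonsyn_snp",
                    Category.STOP_GAIN: "stop_gain",
                    Category.STOP_LOSS: "nonsyn_snp"}[cons.category]
            return off, ref, alt, kind
        self.used_offsets.discard(off)
        return None


@dataclass
class StrainData:
    """Everything simulate_strains emits."""

    calls: dict[tuple[str, str], list[VariantCall]]
    evidence: dict[tuple[str, str], SiteEvidence]
    ledger: TruthLedger
    strains: list[str]


def _genomic_allele(cds: CodingSequence, offset: int, base: str) -> tuple[int, str]:
    pos = cds.cds_to_genomic[offset]
    if cds.strand == "-":
        base = reverse_complement(base)
    return pos, base


def simulate_strains(reference: ReferenceBundle,
                     config: SimulationConfig) -> StrainData:
    """Plant variants and evidence for every strain in the configured panel.

    Event layering per gene: first panel-wide unresolvable status, then a
    lineage-specific deletion (coverage gap >100 bp in one strain), then a
    duplication signature (every call in one other strain ambiguous), then
    group-shared and strain-private SNPs, planted stop gains, indels, and
    sub-threshold noise calls.  Calls are never emitted inside a strain's
    deleted/unresolved span, and no site receives more than one event.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    strains = config.strains()
    calls: dict[tuple[str, str], list[VariantCall]] = {
        (g.gene_id, s): [] for g in reference.genes for s in strains}
    evidence: dict[tuple[str, str], SiteEvidence] = {}
    rows: list[dict] = []

    def ledger(gene_id, strain, kind, start, end=None, ref="", alt="",
               ambiguous=False, passes=True):
        rows.append({"gene_id": gene_id, "strain": strain, "kind": kind,
                     "cds_start": start, "cds_end": start + 1 if end is None else end,
                     "ref": ref, "alt": alt, "ambiguous": ambiguous,
                     "passes_quality": passes})

    def quality(passing: bool = True) -> float:
        if passing:
            return float(np.round(rng.uniform(11.0, 255.0), 1))
        return float(np.round(rng.uniform(0.0, 10.0), 1))

    for gene in reference.genes:
        cds = reference.cds[gene.gene_id]
        sim = _GeneSim(cds, rng)
        L = len(cds)
        gaps: dict[str, list[tuple[int, int]]] = {s: [] for s in strains}

        unresolvable = rng.random() < config.unresolvable_rate
        if unresolvable:
            start = int(rng.integers(0, max(1, L - 150)))
            end = min(L, start + int(rng.integers(150, 400)))
            for s in strains:
                gaps[s].append((start, end))

        deletion_strain = None
        if not unresolvable and rng.random() < config.deletion_rate:
            deletion_strain = strains[rng.integers(len(strains))]
            span = int(rng.integers(120, min(401, max(121, L - 10))))
            start = int(rng.integers(0, L - span))
            gaps[deletion_strain].append((start, start + span))
            ledger(gene.gene_id, deletion_strain, "deletion", start, start + span)

        duplication_strain = None
        if not unresolvable and rng.random() < config.duplication_rate:
            others = [s for s in strains if s != deletion_strain]
            duplication_strain = others[rng.integers(len(others))]

        def emit_snp(strain, off, ref, alt, kind, ambiguous=False, passes=True):
            if _in_intervals(off, gaps[strain]):
                return
            ambiguous = ambiguous or strain == duplication_strain
            pos, genomic_alt = _genomic_allele(cds, off, alt)
            genomic_ref = reference.genome[gene.chrom][pos - 1]
            calls[(gene.gene_id, strain)].append(VariantCall(
                chrom=gene.chrom, pos=pos, ref_allele=genomic_ref,
                alt_allele=genomic_alt, quality=quality(passes), strain=strain,
                kind="snp", ambiguous=ambiguous))
            ledger(gene.gene_id, strain, kind, off, ref=ref, alt=alt,
                   ambiguous=ambiguous, passes=passes)

        # group-shared and private substitutions
        for group in config.strain_groups:
            members = group.strain_names()
            lam = group.snp_rate_per_kb * L / 1000.0
            n_shared = rng.poisson(lam * group.shared_fraction)
            for _ in range(n_shared):
                drawn = sim.draw_snp()
                if drawn is None:
                    continue
                off, ref, alt, kind = drawn
                for s in members:
                    emit_snp(s, off, ref, alt, kind)
            for s in members:
                n_private = rng.poisson(lam * (1.0 - group.shared_fraction))
                for _ in range(n_private):
                    drawn = sim.draw_snp()
                    if drawn is None:
                        continue
                    off, ref, alt, kind = drawn
                    emit_snp(s, off, ref, alt, kind)

        # planted premature stops; lab-group stops may be group-shared
        if rng.random() < config.stop_gain_rate:
            candidates = [c for c in _stop_gain_candidates(cds.sequence)
                          if c[0] not in sim.used_offsets]
            if candidates:
                off, alt = candidates[rng.integers(len(candidates))]
                sim.used_offsets.add(off)
                ref = cds.sequence[off]
                group = config.strain_groups[rng.integers(len(config.strain_groups))]
                members = group.strain_names()
                if len(members) > 1 and rng.random() < group.shared_fraction:
                    targets = members
                else:
                    targets = [members[rng.integers(len(members))]]
                for s in targets:
                    emit_snp(s, off, ref, alt, "stop_gain")

        # short indels (1-50 bp)
        if rng.random() < config.indel_rate:
            strain = strains[rng.integers(len(strains))]
            length = int(rng.integers(1, 51))
            signed = length if rng.random() < 0.5 else -length
            off = sim.draw_offset(forbidden_intervals=gaps[strain])
            if off is not None and off + abs(signed) + 1 < L:
                kind = "frameshift_indel" if length % 3 else "inframe_indel"
                pos = cds.cds_to_genomic[off]
                anchor = reference.genome[gene.chrom][pos - 1]
                if signed > 0:
                    ref_allele, alt_allele = anchor, anchor + _random_dna(rng, length)
                else:
                    chrom_seq = reference.genome[gene.chrom]
                    ref_allele = chrom_seq[pos - 1:pos - 1 + length + 1]
                    alt_allele = anchor
                calls[(gene.gene_id, strain)].append(VariantCall(
                    chrom=gene.chrom, pos=pos, ref_allele=ref_allele,
                    alt_allele=alt_allele, quality=quality(), strain=strain,
                    kind="indel", indel_length=signed,
                    ambiguous=strain == duplication_strain))
                ledger(gene.gene_id, strain, kind, off, off + abs(signed),
                       ref=ref_allele, alt=alt_allele)

        # duplication signature: every call ambiguous, at least two calls
        if duplication_strain is not None:
            existing = [c for c in calls[(gene.gene_id, duplication_strain)]
                        if c.kind == "snp"]
            needed = max(0, 2 - len(existing))
            for _ in range(needed):
                drawn = sim.draw_snp()
                if drawn is None:
                    break
                off, ref, alt, kind = drawn
                emit_snp(duplication_strain, off, ref, alt, kind, ambiguous=True)
            if calls[(gene.gene_id, duplication_strain)]:
                ledger(gene.gene_id, duplication_strain, "duplication", 0, L)

        # sub-threshold noise calls (removed by the quality filter)
        if config.low_quality_rate_per_kb > 0:
            for s in strains:
                for _ in range(rng.poisson(config.low_quality_rate_per_kb * L / 1000.0)):
                    drawn = sim.draw_snp()
                    if drawn is None:
                        continue
                    off, ref, alt, kind = drawn
                    emit_snp(s, off, ref, alt, kind, passes=False)

        for s in strains:
            evidence[(gene.gene_id, s)] = SiteEvidence(
                gene_id=gene.gene_id, strain=s, cds_length=L,
                unresolved_intervals=gaps[s])

    ledger_df = pd.DataFrame(rows, columns=LEDGER_COLUMNS)
    return StrainData(calls=calls, evidence=evidence,
                      ledger=TruthLedger(ledger_df), strains=strains)


# ---------------------------------------------------------------------------
# wild-isolate simulation


@dataclass
class IsolateSet:
    pairs: list[IsolateAllelePair]
    provenance: pd.DataFrame  # isolate_id, gene_id, allele, source ('novel' or strain)


def build_strain_catalog(reference: ReferenceBundle, data: StrainData,
                         config: SimulationConfig,
                         genes: list[str] | None = None) -> StrainCatalog:
    """Reconstruct per-strain haplotypes from the emitted quality-passing,
    unambiguous SNP calls."""
    catalog = StrainCatalog(strains=config.strain_catalog_info())
    gene_ids = genes if genes is not None else [g.gene_id for g in reference.genes]
    for gid in gene_ids:
        cds = reference.cds[gid]
        for strain in data.strains:
            snps = []
            for c in data.calls[(gid, strain)]:
                if c.kind != "snp" or c.quality <= 10 or c.ambiguous:
                    continue
                off = cds.genomic_to_cds[c.pos]
                ref, alt = c.ref_allele, c.alt_allele
                if cds.strand == "-":
                    ref, alt = reverse_complement(ref), reverse_complement(alt)
                snps.append((off, ref, alt))
            catalog.add(gid, strain, reconstruct_haplotype(cds.sequence, snps))
    return catalog


def simulate_isolates(reference: ReferenceBundle, catalog: StrainCatalog,
                      n_isolates: int, novel_allele_rate: float, seed: int,
                      genes: list[str] | None = None,
                      subspecies: tuple[str, ...] = ("domesticus", "musculus"),
                      ) -> IsolateSet:
    """Two alleles per isolate per gene, drawn from strain haplotypes; with
    probability ``novel_allele_rate`` an allele is mutated until it differs
    from every strain haplotype of that gene ("novel" provenance)."""
    if not 0.0 <= novel_allele_rate <= 1.0:
        raise ConfigurationError("novel_allele_rate must be in [0,1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    gene_ids = genes if genes is not None else sorted({g for g, _ in catalog.haplotypes})
    strain_names = sorted(catalog.strains)
    pairs, prov = [], []
    for ii in range(n_isolates):
        isolate_id = f"isolate_{ii + 1:03d}"
        subsp = subspecies[ii % len(subspecies)]
        for gid in gene_ids:
            haps = {s: catalog.haplotypes[(gid, s)] for s in strain_names
                    if (gid, s) in catalog.haplotypes}
            alleles = []
            for ai in (1, 2):
                source = strain_names[rng.integers(len(strain_names))]
                allele = haps[source]
                if rng.random() < novel_allele_rate:
                    existing = set(haps.values())
                    while allele in existing:
                        off = int(rng.integers(3, len(allele) - 3))
                        alt = BASES[rng.integers(4)]
                        allele = allele[:off] + alt + allele[off + 1:]
                    source = "novel"
                alleles.append(allele)
                prov.append({"isolate_id": isolate_id, "gene_id": gid,
                             "allele": ai, "source": source})
            pairs.append(IsolateAllelePair(isolate_id, subsp, gid,
                                           alleles[0], alleles[1]))
    return IsolateSet(pairs=pairs, provenance=pd.DataFrame(prov))
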