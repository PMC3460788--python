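"""End-to-end orchestration: simulate, annotate, parse, summarise, classify,
partition, match and score in dependency order with one seed.

Each stage writes its outputs under the run directory and a manifest records
seed, thresholds and stage order, so a rerun with the same configuration
reproduces every stochastic output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .accuracy import report_dict, score_calls
from .consequence import (DEFAULT_QUALITY_THRESHOLD, annotate_calls,
                          filter_quality)
from .domain_partition import DomainAnnotation, pooled_domain_rates
from .functional_repertoire import (aggregate_repertoire, detect_frameshifts,
                                    detect_truncations, per_strain_counts,
                                    status_table)
from .gene_models import write_gene_models, write_genome
from .haplotype_match import match_matrix
from .io_formats import write_evidence, write_tsv, write_vcf
from .repertoire_qc import (DEFAULT_MAX_EXCLUDED, run_cascade)
from .synthetic_data import (SimulationConfig, StrainData, build_strain_catalog,
                             generate_reference, simulate_isolates,
                             simulate_strains)
from .variation_stats import (annotations_frame, density_matrix,
                              subfamily_density, summary_table)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str = "vrvar_run"
    seed: int = 0
    quality_threshold: float = DEFAULT_QUALITY_THRESHOLD
    max_excluded: int = DEFAULT_MAX_EXCLUDED
    n_isolates: int = 14
    novel_allele_rate: float = 0.5
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def with_seed(self) -> "RunConfig":
        from dataclasses import replace
        return replace(self, simulation=replace(self.simulation, seed=self.seed))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class PipelineResult:
    out_dir: Path
    parsed: object
    annotations: pd.DataFrame
    summary: pd.DataFrame
    repertoire: pd.DataFrame
    manifest: dict


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage on a freshly simulated repertoire."""
    config = config.with_seed()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    warnings: list[dict] = []
    stages: list[str] = []

    def stage(name: str):
        stages.append(name)
        log.info("stage: %s", name)

    # --- simulate -----------------------------------------------------------
    stage("simulate")
    reference = generate_reference(sim)
    data = simulate_strains(reference, sim)
    write_genome(reference.genome, out / "genome.fa")
    write_gene_models(reference.genes, out / "genes.gff3")
    write_vcf(data.calls, data.strains, sorted(reference.genome),
              out / "calls.vcf")
    write_evidence(data.evidence, out / "evidence.bed")
    data.ledger.write(out / "truth_ledger.tsv")
    write_tsv(pd.DataFrame(
        [{"gene_id": g, "tm_start": t}
         for g, t in sorted(reference.domain_annotations.items())]),
        out / "domains.tsv")

    cds_lengths = reference.cds_lengths()
    gene_of_pos = {}
    for g in reference.genes:
        for pos in reference.cds[g.gene_id].genomic_to_cds:
            gene_of_pos[(g.chrom, pos)] = g.gene_id

    # --- annotate -----------------------------------------------------------
    stage("annotate")
    all_calls = [c for calls in data.calls.values() for c in calls]
    annotated = annotate_calls(
        all_calls, reference.cds,
        lambda c: gene_of_pos.get((c.chrom, c.pos)),
        threshold=config.quality_threshold)
    annotations = annotations_frame(annotated)
    write_tsv(annotations, out / "consequences.tsv")

    # --- parse --------------------------------------------------------------
    stage("parse")
    passing = {key: filter_quality(calls, config.quality_threshold)
               for key, calls in data.calls.items()}
    parsed = run_cascade(passing, data.evidence, strains=data.strains,
                         max_excluded=config.max_excluded)
    write_tsv(parsed.to_frame(), out / "status_matrix.tsv")

    # --- stats --------------------------------------------------------------
    stage("stats")
    summary = summary_table(parsed, annotations, data.evidence, cds_lengths)
    write_tsv(summary, out / "strain_summary.tsv")
    gene_order = [g.gene_id for g in reference.genes]  # cluster/phylogeny order
    dm = density_matrix(parsed, annotations, cds_lengths, gene_order)
    dm.values.to_csv(out / "density_matrix.tsv", sep="\t")
    dm.markers.to_csv(out / "density_markers.tsv", sep="\t")
    subfam = {g.gene_id: g.subfamily for g in reference.genes}
    pools = {}
    for group in sim.strain_groups:
        pools.setdefault(group.strain_class, []).extend(group.strain_names())
    write_tsv(subfamily_density(parsed, annotations, data.evidence,
                                cds_lengths, subfam, pools),
              out / "subfamily_density.tsv")

    # --- repertoire ---------------------------------------------------------
    stage("repertoire")
    truncations = detect_truncations(annotations, cds_lengths)
    frameshifts = detect_frameshifts(annotated)
    statuses = status_table(parsed, truncations, frameshifts)
    write_tsv(statuses, out / "functional_status.tsv")
    write_tsv(aggregate_repertoire(statuses), out / "repertoire_summary.tsv")
    write_tsv(per_strain_counts(statuses), out / "per_strain_status.tsv")
    write_tsv(pd.DataFrame([{
        "gene_id": e.gene_id, "strain": e.strain, "cds_offset": e.cds_offset,
        "codon_index": e.codon_index,
        "relative_position": round(e.relative_position, 4),
        "near_3prime": e.near_3prime} for e in truncations]),
        out / "truncations.tsv")

    # --- domains ------------------------------------------------------------
    stage("domains")
    v2r_domains = {g: DomainAnnotation(g, t)
                   for g, t in reference.domain_annotations.items()}
    if v2r_domains:
        write_tsv(pooled_domain_rates(cds_lengths, v2r_domains, annotations),
                  out / "domain_rates.tsv")

    # --- match --------------------------------------------------------------
    stage("match")
    catalog_genes = parsed.genes_for_strain(data.strains[0])[:40]
    catalog = build_strain_catalog(reference, data, sim, genes=catalog_genes)
    isolates = simulate_isolates(reference, catalog, config.n_isolates,
                                 config.novel_allele_rate, config.seed,
                                 genes=catalog_genes)
    table, match_summary = match_matrix(isolates.pairs, catalog, catalog_genes)
    write_tsv(table, out / "isolate_matches.tsv")
    write_tsv(match_summary, out / "isolate_match_summary.tsv")

    # --- accuracy -----------------------------------------------------------
    stage("accuracy")
    # score one strain's reconstructed haplotypes against the planted truth
    strain = data.strains[-1]
    called, truth = set(), set()
    offset = 0
    region = 0
    for gid in catalog_genes:
        cds = reference.cds[gid]
        hap = catalog.haplotypes[(gid, strain)]
        called |= {(offset + i, b) for (i, b) in
                   ((i, hap[i]) for i in range(len(hap)))
                   if hap[i] != cds.sequence[i]}
        led = data.ledger.events
        mask = ((led.gene_id == gid) & (led.strain == strain)
                & led.kind.isin(["syn_snp", "nonsyn_snp", "stop_gain"])
                & led.passes_quality & ~led.ambiguous)
        truth |= {(offset + int(r.cds_start), str(r.alt))
                  for r in led[mask].itertuples(index=False)}
        offset += len(cds)
        region += len(cds)
    report = score_calls(called, truth, region)
    (out / "accuracy.json").write_text(json.dumps(report_dict(report), indent=2))

    # --- manifest -----------------------------------------------------------
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "quality": config.quality_threshold,
            "mapq": 30,
            "ambiguous_fraction": 0.5,
            "deletion_run_bp": 100,
            "max_excluded": config.max_excluded,
        },
        "stages": stages,
        "n_genes": sim.n_genes,
        "strains": data.strains,
        "checksums": {p.name: _checksum(p) for p in sorted(out.iterdir())
                      if p.suffix in {".tsv", ".vcf", ".fa", ".gff3", ".bed",
                                      ".json"}},
        "warnings": warnings,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return PipelineResult(out_dir=out, parsed=parsed, annotations=annotations,
                          summary=summary,
                          repertoire=aggregate_repertoire(statuses),
                          manifest=manifest)
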