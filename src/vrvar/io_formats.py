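"""On-disk interchange for the pipeline's intermediate products.

Variant calls travel as a minimal multi-sample VCF (CHROM, POS, REF, ALT,
QUAL per record — calls with differing qualities across strains are written
as separate records — and per-strain GT plus an AM ambiguity flag in FORMAT);
site evidence as a BED-like table of unresolved CDS intervals per gene and
strain; the truth ledger and all statistics as TSV.  Reading the VCF goes
through pysam so the dialect stays honest.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pysam

from .consequence import VariantCall
from .repertoire_qc import DEFAULT_MAPQ_THRESHOLD, SiteEvidence

VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=KIND,Number=1,Type=String,Description="Variant kind: snp or indel">
##INFO=<ID=ILEN,Number=1,Type=Integer,Description="Signed indel length in bp">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AM,Number=1,Type=Integer,Description="Ambiguous call flag">
"""


def write_vcf(calls_by_gene_strain: dict, strains: list[str], contigs: list[str],
              path) -> None:
    records: dict[tuple, dict] = {}
    for (gene_id, strain), calls in calls_by_gene_strain.items():
        for c in calls:
            key = (c.chrom, c.pos, c.ref_allele, c.alt_allele, c.quality,
                   c.kind, c.indel_length)
            rec = records.setdefault(key, {})
            rec[strain] = c
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(strains) + "\n")
        for key in sorted(records, key=lambda k: (k[0], k[1], k[3])):
            chrom, pos, ref, alt, qual, kind, ilen = key
            info = f"KIND={kind}" + (f";ILEN={ilen}" if kind == "indel" else "")
            samples = []
            for s in strains:
                call = records[key].get(s)
                if call is None:
                    samples.append("0/0:0")
                else:
                    samples.append(f"1/1:{int(call.ambiguous)}")
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t{qual}\t.\t{info}\t"
                     f"GT:AM\t" + "\t".join(samples) + "\n")


def read_vcf(path) -> dict[tuple[str, str], list[VariantCall]]:
    """Calls keyed by (chrom, strain); gene attribution is the caller's job."""
    out: dict[tuple[str, str], list[VariantCall]] = {}
    with pysam.VariantFile(str(path)) as vcf:
        strains = list(vcf.header.samples)
        for rec in vcf:
            kind = rec.info.get("KIND", "snp")
            ilen = int(rec.info.get("ILEN", 0))
            for s in strains:
                sample = rec.samples[s]
                if sample["GT"] != (1, 1):
                    continue
                # htslib stores QUAL as float32; restore the written precision
                out.setdefault((rec.chrom, s), []).append(VariantCall(
                    chrom=rec.chrom, pos=rec.pos, ref_allele=rec.ref,
                    alt_allele=rec.alts[0], quality=round(float(rec.qual), 1),
                    strain=s, kind=kind, indel_length=ilen,
                    ambiguous=bool(sample["AM"])))
    return out


EVIDENCE_COLUMNS = ["gene_id", "start", "end", "strain", "cds_length",
                    "mapq_threshold"]


def write_evidence(evidence: dict[tuple[str, str], SiteEvidence], path) -> None:
    """Unresolved CDS intervals (0-based half-open), BED-style columns.

    Fully resolved gene x strain cells are written as a zero-length sentinel
    interval (start = end = -1) so the full cell matrix round-trips."""
    rows = []
    for (gene_id, strain), ev in sorted(evidence.items()):
        if ev.unresolved_intervals:
            for s, e in ev.unresolved_intervals:
                rows.append((gene_id, s, e, strain, ev.cds_length, ev.mapq_threshold))
        else:
            rows.append((gene_id, -1, -1, strain, ev.cds_length, ev.mapq_threshold))
    pd.DataFrame(rows, columns=EVIDENCE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_evidence(path) -> dict[tuple[str, str], SiteEvidence]:
    df = pd.read_csv(path, sep="\t")
    out: dict[tuple[str, str], SiteEvidence] = {}
    for row in df.itertuples(index=False):
        key = (row.gene_id, row.strain)
        if key not in out:
            out[key] = SiteEvidence(row.gene_id, row.strain, int(row.cds_length),
                                    [], int(row.mapq_threshold))
        if row.start >= 0:
            ev = out[key]
            ev.unresolved_intervals = sorted(
                ev.unresolved_intervals + [(int(row.start), int(row.end))])
    return out


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
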