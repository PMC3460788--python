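# Methods

## The analysis

`vrvar` analyses coding variation in the mouse vomeronasal receptor (VR)
repertoire — the V1R, V2R and formyl-peptide receptor (FPR) families —
across a panel of inbred strains re-sequenced against the C57BL/6J
reference. Because these receptors sit in tightly clustered, highly
homologous genomic arrays, short-read variant calls in them are unusually
fragile: reads mis-map between paralogues, lineage-specific deletions appear
as coverage gaps, and duplicated loci fold two haplotypes onto one reference
position. The package therefore couples consequence annotation with an
explicit quality-parsing cascade before any statistic is computed.

The stages, in dependency order:

1. **Gene models and CDS construction** (`gene_models`). CDS exons (GFF3,
   1-based inclusive) are spliced out of the genome FASTA; minus-strand
   genes are reverse-complemented so CDS offset 0 (0-based half-open
   internally) is the highest exonic genomic coordinate. The coordinate map
   is a bijection between exonic genomic positions and CDS offsets. Two
   models with identical exon sets are collapsed to the lexicographically
   first gene id, since they describe one locus twice.
2. **Consequence annotation** (`consequence`). Calls with quality score
   strictly greater than 10 are kept. Each coding SNP is classified
   synonymous / non-synonymous / stop-gain / stop-loss by codon substitution
   under the standard nuclear code; ambiguity-flagged calls pass through as
   `ambiguous` (their allele identity is untrusted), as do SNPs in genes
   whose CDS length is not a multiple of 3. Indels of 1–50 bp are frameshift
   iff their length is not a multiple of 3; longer events are out of the
   calling range. In all aggregates, stop gains are counted inside the
   non-synonymous tally and also reported separately as truncating SNPs —
   this makes the per-strain summary-table arithmetic self-consistent.
3. **Parsing cascade** (`repertoire_qc`). Per gene × strain, in precedence
   order: *duplication* if strictly more than 50% of its SNP calls are
   ambiguous (two co-mapping haplotypes in an inbred, hence homozygous,
   genome); *deletion* if the strain carries an unresolved coverage run
   strictly longer than 100 bp over an interval at which at least one other
   strain is fully resolved; otherwise *unresolved* if any base of the CDS
   lacks coverage at the MAPQ > 30 threshold (coverage of the *entire*
   coding region is required); otherwise *included*. Finally, any gene
   excluded in more than 3 strains for any reason is removed from every
   strain's analyzable set, while per-strain reasons are preserved for
   reporting.
4. **Summary statistics** (`variation_stats`). Per-strain SNP counts,
   non-synonymous fractions, truncating counts (share of non-synonymous
   SNPs), private SNPs (a gene/site/alt-allele triple observed in exactly
   one strain among strains where the gene survived parsing), codon-spacing
   densities ((bp/3)/SNPs, reported to the nearest integer), non-syn:syn
   ratios (2 decimals), the gene × strain non-syn-per-kb matrix with
   duplication/deletion cells carried as markers rather than zeros, and
   per-subfamily mean densities over resolved kb with the standard error
   across the strain pool. Resolved bp per strain sums |CDS| minus
   unresolved bases over included genes; the unresolved percentage is taken
   against the pre-parsing total.
5. **Functional repertoire** (`functional_repertoire`). One status per
   gene × strain in the order duplication > deletion > truncated >
   frameshift > intact, applied identically when aggregating "affected in at
   least one strain" across the panel. Truncation is an evidence category,
   not a pseudogene call; stop gains in the final 5% of the CDS are flagged
   `near_3prime` but still counted. Compensatory frameshift restoration is
   not modeled.
6. **Domain partition** (`domain_partition`). V2R coding sequences are split
   at a supplied CDS offset of the first trans-membrane helix (the long
   extracellular N-terminal domain precedes it); SNPs are assigned by
   nucleotide offset with a half-open boundary, so a variant exactly at the
   boundary is trans-membrane. Counts are normalised per domain kb. The
   boundary is consumed as an annotation, not predicted: hydropathy
   prediction is outside the package's scope, and synthetic genes carry
   generated boundaries.
7. **Haplotype matching** (`haplotype_match`). Per-strain haplotypes are the
   reference CDS with each unambiguous SNP's alternate substituted
   (conflicting alternates at one site are an error in an inbred strain).
   A wild-caught isolate, contributing two sequenced alleles per gene,
   matches a strain when at least one allele is exactly identical to the
   strain haplotype — full-string equality with no alignment, because
   haplotypes, not alignments, are being compared. Among multiple matches
   the precedence is wild-derived strain of the same subspecies, then
   laboratory-derived strains, then wild-derived strains of another
   subspecies; remaining ties break lexicographically and are flagged in the
   output, since no biological criterion distinguishes them.
8. **Accuracy assessment** (`accuracy`). Called vs gold-standard SNP sets
   keyed by (position, alternate allele) over a coordinate-matched region:
   false-positive rate over called SNPs, false-negative rate over true SNPs,
   base-pair accuracy 1 − (fp + fn)/region bp. These denominators are the
   convention under which all three headline numbers are reportable from one
   comparison, and are stated in the report. A call at a true site with the
   wrong alternate is one false positive plus one false negative.

## The synthetic-data generator

`synthetic_data` emulates the structure of the real inputs so the whole
chain is testable without external downloads.

* **Reference.** One chromosome per cluster; each cluster's genes derive
  from a common ancestral CDS (ATG start, no internal stops, one terminal
  stop) by replacing disjoint sets of codons. With k mutated codons per gene
  the pairwise difference is bounded by 6k nucleotides, which guarantees the
  configured within-cluster identity floor (default 0.95); the floor is
  verified in tests with an independent global aligner. V2R-like clusters
  are multi-exonic (introns 100–300 bp), V1R/FPR-like clusters single-exon;
  strand is drawn per gene. Gene sizes follow the families' typical coding
  lengths (V1R ≈ 280–320 codons, V2R ≈ 800–900, FPR ≈ 330–360); V2R genes
  get a trans-membrane boundary at ~70% of the CDS. Defaults produce 368
  genes in 92 clusters of 4, matching the scale of the 366-gene reference
  repertoire.
* **Strain panel.** Default groups mirror the study panel: 13
  laboratory-derived strains sharing 80% of their SNPs, plus four divergent
  wild-derived strains (one group each, everything group-specific) with
  per-kb SNP rates 1.5/4.7/5.0/13.2 taken from the published per-strain
  counts over resolved kb. SNP alternates are drawn uniformly; substitutions
  that would create a stop are redrawn, and premature stops are planted
  separately (per-gene probability 0.05) so recovery is exactly scoreable —
  lab-planted stops may be group-shared. Indels are 1–50 bp (probability
  0.05/gene), deletions are pure coverage gaps of 120–400 bp in one strain
  (0.05/gene; no breakpoint model, because the pipeline only ever sees the
  gap), duplications are an allele-mixture signature — every call of one
  strain flagged ambiguous, with at least two calls guaranteed (0.05/gene) —
  because the pipeline only ever observes the call-level signature, not
  extra copies. A further 3% of genes are unresolvable panel-wide (shared
  coverage gaps), emulating homology-driven mapping failure, and 0.1
  sub-threshold noise calls per kb exercise the quality filter. No site
  receives more than one event, so emitted calls per gene × strain equal the
  truth-ledger rows exactly.
* **Isolates.** Each simulated wild isolate carries two alleles per gene,
  each copied from a random strain haplotype; with the configured
  novel-allele probability an allele is mutated until it differs from every
  strain haplotype, and provenance is recorded. Phasing between genes is
  not modeled, as nothing downstream consumes it.

What the generator does *not* emulate: read-level errors and base
qualities, mapping itself, realistic chromosome scale, linkage between
clusters, site-frequency spectra under selection, or partially ambiguous
duplication signatures near the 50% threshold. Passing recovery tests
therefore show that the cascade's decision rules are implemented exactly as
specified, not that the thresholds are optimal on real read data.

## Numerical and design choices

* Coordinates: 1-based inclusive externally (GFF/VCF), 0-based half-open
  internally; minus-strand alleles complemented at the CDS boundary.
* Thresholds are strict inequalities where stated: quality > 10, MAPQ > 30
  (a read at exactly 30 does not resolve a site), ambiguous fraction > 0.5
  (exactly half is not a duplication), deletion run > 100 bp (exactly 100
  is only "incomplete"), excluded in > 3 strains.
* The duplication denominator is SNP calls in that gene × strain (sites
  with any call); indel calls do not enter it.
* Zero denominators signal explicitly (flagged 0% rows, `ZeroDivisionError`
  for codon spacings and ratios, NaN ratio for a domain without synonymous
  SNPs) rather than propagating silently.
* Percentages round to one decimal for table reporting; ratios to two.
* Randomness flows from a single integer seed through named substreams
  (reference / strains / isolates), so stage outputs are byte-reproducible
  under a fixed configuration; the run manifest records seed, thresholds and
  output checksums.
* Significance machinery (ANOVA, t-tests, PCA, clustering and heat-map
  rendering) is deliberately not reimplemented here; the package emits tidy
  tables that standard tools consume.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the generator at reduced
scale — typically 20–100 genes and 7–17 strains, with a 100-gene × 8-strain
panel for planted-event recovery and 100 isolates × 20 genes for matching —
sizes at which every planted signature is still individually verifiable
against the ledger. Printed-count arithmetic (summary-table totals and
percentages, codon densities 273/634/363/325, ratios 0.54/0.49, the 2.3×
enrichment) is exact and scale-free. The published BAC-comparison accuracy
triple (1.3% / 0.5% / 99.95%) depends on gold-standard SNP lists that are
not distributed, so the accuracy module is instead checked against its
closed form, including the 4-errors-in-8-kb case that yields 99.95%.

## Known limitations

* Ambiguity is consumed as a per-call flag; the read-proportion rule that
  produces it upstream is not re-derived.
* The deletion caller requires at least one fully resolved witness strain
  over the gap; a deletion shared by every strain is indistinguishable from
  homology-driven mapping failure and is classed unresolved.
* Exact-string haplotype matching tolerates no missing bases; an isolate
  allele with an indel can only match trivially identical strings.
* Truncation/frameshift statuses are evidence categories; rescue by
  alternative splicing or near-3′ stops may leave receptors functional.
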