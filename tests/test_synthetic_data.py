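"""The generator: determinism, planted signatures, and the truth ledger."""

import numpy as np
import pytest
from Bio.Align import PairwiseAligner

from vrvar.consequence import Category, classify_substitution
from vrvar.synthetic_data import (ConfigurationError, SimulationConfig,
                                  StrainGroup, build_strain_catalog,
                                  generate_reference, simulate_isolates,
                                  simulate_strains)


class TestGenerateReference:
    def test_single_gene_cds_equals_genomic_substring(self):
        cfg = SimulationConfig(n_clusters=1, genes_per_cluster=1,
                               n_exons_range=(1, 1), fraction_v2r=0,
                               fraction_fpr=0, strand_fraction_minus=0.0,
                               seed=1)
        ref = generate_reference(cfg)
        [gene] = ref.genes
        (start, end) = gene.exons[0]
        assert gene.strand == "+" and len(gene.exons) == 1
        assert ref.cds[gene.gene_id].sequence == \
            ref.genome[gene.chrom][start - 1:end]

    def test_same_seed_reproduces_byte_identical_reference(self):
        cfg = SimulationConfig(n_clusters=3, genes_per_cluster=2, seed=42)
        a, b = generate_reference(cfg), generate_reference(cfg)
        assert a.genome == b.genome
        assert a.genes == b.genes
        assert {g: c.sequence for g, c in a.cds.items()} == \
               {g: c.sequence for g, c in b.cds.items()}

    def test_within_cluster_identity_verified_by_pairwise_alignment(self):
        """All six pairwise identities in a 4-gene cluster, measured by an
        independent global aligner, stay at or above the configured floor."""
        cfg = SimulationConfig(n_clusters=1, genes_per_cluster=4,
                               within_cluster_identity=0.95, fraction_v2r=0,
                               fraction_fpr=0, seed=13)
        ref = generate_reference(cfg)
        seqs = [ref.cds[g.gene_id].sequence for g in ref.genes]
        aligner = PairwiseAligner(mode="global", match_score=1,
                                  mismatch_score=0, gap_score=-2)
        for i in range(4):
            for j in range(i + 1, 4):
                identity = aligner.score(seqs[i], seqs[j]) / len(seqs[i])
                assert identity >= 0.95

    def test_cds_well_formed(self, reference):
        stops = {"TAA", "TAG", "TGA"}
        strands = set()
        for g in reference.genes:
            seq = reference.cds[g.gene_id].sequence
            assert len(seq) % 3 == 0
            assert seq.startswith("ATG") and seq[-3:] in stops
            # no internal stops
            assert not any(seq[i:i + 3] in stops
                           for i in range(3, len(seq) - 3, 3))
            strands.add(g.strand)
        assert strands == {"+", "-"}

    def test_identity_one_with_multiple_genes_is_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(within_cluster_identity=1.0,
                             genes_per_cluster=2).validate()

    def test_bad_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(strand_fraction_minus=1.5).validate()


class TestSimulateStrains:
    def test_all_rates_zero_yields_no_variants_and_complete_evidence(self):
        cfg = SimulationConfig(
            n_clusters=3, genes_per_cluster=2, seed=3,
            strain_groups=(StrainGroup("lab", 2, 0.0, 0.0),),
            stop_gain_rate=0, indel_rate=0, deletion_rate=0,
            duplication_rate=0, unresolvable_rate=0, low_quality_rate_per_kb=0)
        data = simulate_strains(generate_reference(cfg), cfg)
        assert sum(len(v) for v in data.calls.values()) == 0
        assert len(data.ledger.events) == 0
        assert all(not ev.unresolved_intervals for ev in data.evidence.values())

    def test_same_seed_reproduces_identical_outputs(self, small_config,
                                                    reference):
        a = simulate_strains(reference, small_config)
        b = simulate_strains(reference, small_config)
        assert a.ledger.events.equals(b.ledger.events)
        assert a.calls == b.calls
        assert {k: e.unresolved_intervals for k, e in a.evidence.items()} == \
               {k: e.unresolved_intervals for k, e in b.evidence.items()}

    def test_call_counts_equal_ledger_entries(self, strain_data):
        """Conservation: emitted calls per gene x strain match the ledger's
        SNP/indel rows exactly."""
        for (gene, strain), calls in strain_data.calls.items():
            assert len(calls) == strain_data.ledger.call_count(gene, strain)

    def test_duplication_signature_majority_ambiguous(self, strain_data):
        led = strain_data.ledger.events
        dup_pairs = set(zip(led[led.kind == "duplication"].gene_id,
                            led[led.kind == "duplication"].strain))
        assert dup_pairs, "fixture must plant at least one duplication"
        for gene, strain in dup_pairs:
            calls = [c for c in strain_data.calls[(gene, strain)]
                     if c.kind == "snp"]
            frac = sum(c.ambiguous for c in calls) / len(calls)
            assert frac > 0.5

    def test_deletion_signature_gap_specific_to_affected_strain(self,
                                                                rich_data):
        strain_data = rich_data
        led = strain_data.ledger.events
        dels = led[led.kind == "deletion"]
        assert len(dels), "fixture must plant at least one deletion"
        for row in dels.itertuples(index=False):
            ev = strain_data.evidence[(row.gene_id, row.strain)]
            runs = [e - s for s, e in ev.unresolved_intervals]
            assert max(runs) > 100
            for other in strain_data.strains:
                if other == row.strain:
                    continue
                assert strain_data.evidence[(row.gene_id, other)].resolved_at(
                    int(row.cds_start), int(row.cds_end))

    def test_planted_snps_consistent_with_reference_alleles(self, reference,
                                                            strain_data):
        for calls in strain_data.calls.values():
            for c in calls:
                if c.kind != "snp":
                    continue
                assert reference.genome[c.chrom][c.pos - 1] == c.ref_allele
                assert c.alt_allele != c.ref_allele

    def test_planted_stop_gains_round_trip_through_classifier(self, reference,
                                                              strain_data):
        led = strain_data.ledger.events
        stops = led[led.kind == "stop_gain"]
        assert len(stops), "fixture must plant at least one stop gain"
        for row in stops.itertuples(index=False):
            cds = reference.cds[row.gene_id]
            cons = classify_substitution(cds.sequence, int(row.cds_start),
                                         row.alt)
            assert cons.category is Category.STOP_GAIN

    def test_lab_strains_share_snps_wild_snps_are_group_specific(self,
                                                                 strain_data):
        led = strain_data.ledger.events
        snps = led[led.kind.isin(["syn_snp", "nonsyn_snp", "stop_gain"])
                   & led.passes_quality]
        lab = snps[snps.strain.str.startswith("lab")]
        key = ["gene_id", "cds_start", "alt"]
        lab_sharing = lab.groupby(key).strain.nunique()
        # with shared_fraction 0.8 a large share of lab sites recur group-wide
        assert (lab_sharing > 1).mean() > 0.3
        wild = snps[~snps.strain.str.startswith("lab")]
        wild_sharing = wild.groupby(key).strain.nunique()
        assert (wild_sharing == 1).all()

    def test_indel_lengths_within_calling_range(self, strain_data):
        led = strain_data.ledger.events
        indels = led[led.kind.isin(["frameshift_indel", "inframe_indel"])]
        lengths = (indels.cds_end - indels.cds_start).astype(int)
        assert ((lengths >= 1) & (lengths <= 50)).all()
        fs = indels[indels.kind == "frameshift_indel"]
        assert ((fs.cds_end - fs.cds_start) % 3 != 0).all()


@pytest.fixture(scope="module")
def catalog(reference, strain_data, small_config):
    genes = [g.gene_id for g in reference.genes[:6]]
    return build_strain_catalog(reference, strain_data, small_config,
                                genes=genes)


class TestSimulateIsolates:
    def test_rate_zero_every_allele_is_a_strain_haplotype(self, reference,
                                                          catalog):
        isolates = simulate_isolates(reference, catalog, 5, 0.0, seed=2)
        haps = set(catalog.haplotypes.values())
        for p in isolates.pairs:
            assert p.allele_1 in haps and p.allele_2 in haps
        assert (isolates.provenance.source != "novel").all()

    def test_rate_one_no_allele_matches_any_haplotype(self, reference,
                                                      catalog):
        from vrvar.haplotype_match import match_matrix, NO_MATCH
        isolates = simulate_isolates(reference, catalog, 5, 1.0, seed=2)
        table, summary = match_matrix(isolates.pairs, catalog)
        assert (table.match == NO_MATCH).all()
        assert (summary.matched_fraction == 0.0).all()

    def test_two_alleles_per_isolate_per_gene(self, reference, catalog):
        isolates = simulate_isolates(reference, catalog, 3, 0.5, seed=2)
        genes = {g for g, _ in catalog.haplotypes}
        counts = isolates.provenance.groupby(["isolate_id", "gene_id"]).size()
        assert (counts == 2).all()
        assert len(counts) == 3 * len(genes)

    def test_matched_fraction_within_binomial_bounds(self, reference, catalog):
        """With novel-allele rate q, a gene matches unless both alleles are
        novel: matched count ~ Binomial(n, 1 - q^2)."""
        from scipy.stats import binom
        from vrvar.haplotype_match import match_matrix
        q = 0.5
        isolates = simulate_isolates(reference, catalog, 100, q, seed=6)
        table, summary = match_matrix(isolates.pairs, catalog)
        n = len(table)
        matched = int((table.match != "no-match").sum())
        lo = binom.ppf(0.005, n, 1 - q ** 2)
        hi = binom.ppf(0.995, n, 1 - q ** 2)
        assert lo <= matched <= hi
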