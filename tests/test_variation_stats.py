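"""Summary statistics: private SNPs, densities, ratios, matrices."""

import numpy as np
import pandas as pd
import pytest

from vrvar import reference_data
from vrvar.repertoire_qc import GeneStrainStatus, Status, aggregate_exclusions
from vrvar.variation_stats import (ANNOT_COLUMNS, codons_per_snp,
                                   density_matrix, find_private_snps,
                                   nonsyn_syn_ratio, subfamily_density)


def make_parsed(genes, strains, excluded=()):
    statuses = {(g, s): GeneStrainStatus(
        g, s, Status.DUPLICATION if (g, s) in excluded else Status.INCLUDED)
        for g in genes for s in strains}
    return aggregate_exclusions(statuses, max_excluded=len(strains))


def ann_row(gene, strain, pos, alt="G", category="nonsynonymous", offset=None):
    return {"gene_id": gene, "strain": strain, "pos": pos,
            "cds_offset": pos - 1 if offset is None else offset,
            "ref": "A", "alt": alt, "category": category}


class TestPrivateSnps:
    def test_snp_in_one_of_three_strains_is_private(self):
        parsed = make_parsed(["g1"], ["a", "b", "c"])
        ann = pd.DataFrame([ann_row("g1", "a", 5)], columns=ANNOT_COLUMNS)
        private = find_private_snps(ann, parsed)
        assert len(private["a"]) == 1 and len(private["b"]) == 0

    def test_same_site_same_alt_in_two_strains_private_to_neither(self):
        parsed = make_parsed(["g1"], ["a", "b", "c"])
        ann = pd.DataFrame([ann_row("g1", "a", 5), ann_row("g1", "b", 5)],
                           columns=ANNOT_COLUMNS)
        private = find_private_snps(ann, parsed)
        assert all(len(private[s]) == 0 for s in "abc")

    def test_same_site_different_alt_is_private_to_both(self):
        parsed = make_parsed(["g1"], ["a", "b"])
        ann = pd.DataFrame([ann_row("g1", "a", 5, alt="G"),
                            ann_row("g1", "b", 5, alt="T")],
                           columns=ANNOT_COLUMNS)
        private = find_private_snps(ann, parsed)
        assert len(private["a"]) == 1 and len(private["b"]) == 1

    def test_matches_brute_force_occurrence_count(self):
        """Randomised fixture: private sets equal counting (site, alt) pairs
        seen in exactly one strain."""
        rng = np.random.default_rng(17)
        strains = ["a", "b", "c", "d"]
        parsed = make_parsed(["g1", "g2"], strains)
        rows = []
        for _ in range(300):
            rows.append(ann_row(rng.choice(["g1", "g2"]), rng.choice(strains),
                                int(rng.integers(1, 60)),
                                alt=rng.choice(list("GT"))))
        ann = pd.DataFrame(rows, columns=ANNOT_COLUMNS).drop_duplicates(
            subset=["gene_id", "strain", "pos", "alt"])
        private = find_private_snps(ann, parsed)
        seen = {}
        for r in ann.itertuples(index=False):
            seen.setdefault((r.gene_id, r.pos, r.alt), set()).add(r.strain)
        brute = {s: sum(1 for who in seen.values() if who == {s}) for s in strains}
        assert {s: len(private[s]) for s in strains} == brute
        # pairwise disjoint by construction of the keying
        keys = [set(map(tuple, private[s][["gene_id", "pos", "alt"]].values))
                for s in strains]
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                assert not keys[i] & keys[j]


class TestDensities:
    @pytest.mark.parametrize("bp,n,expect", [
        (reference_data.VR_CODING_BP_TOTAL, 6394, 273),
        (reference_data.GENOME_CODING_BP_TOTAL, 315094, 634),
        (300, 1, 100),
    ])
    def test_codons_per_snp(self, bp, n, expect):
        assert codons_per_snp(bp, n) == expect

    def test_zero_snps_signals_no_density(self):
        with pytest.raises(ZeroDivisionError):
            codons_per_snp(300, 0)

    def test_strictly_decreasing_in_snp_count(self):
        values = [codons_per_snp(5_000_000, n) for n in (100, 1000, 10000)]
        assert values == sorted(values, reverse=True)


class TestRatios:
    @pytest.mark.parametrize("nonsyn,syn,expect", [
        (reference_data.GENOME_NONSYN_LAB, reference_data.GENOME_SYN_LAB, 0.54),
        (reference_data.GENOME_NONSYN_WILD, reference_data.GENOME_SYN_WILD, 0.49),
        (7, 7, 1.00),
    ])
    def test_nonsyn_syn_ratio(self, nonsyn, syn, expect):
        assert nonsyn_syn_ratio(nonsyn, syn) == expect

    def test_zero_synonymous_undefined(self):
        with pytest.raises(ZeroDivisionError):
            nonsyn_syn_ratio(5, 0)


class TestDensityMatrix:
    def test_cell_arithmetic_and_markers(self):
        parsed = make_parsed(["g1", "g2"], ["a", "b"], excluded={("g2", "b")})
        ann = pd.DataFrame([ann_row("g1", "a", p) for p in (3, 9, 21)],
                           columns=ANNOT_COLUMNS)
        dm = density_matrix(parsed, ann, {"g1": 900, "g2": 600}, ["g1", "g2"])
        assert dm.values.loc["g1", "a"] == pytest.approx(3 / 0.9)
        assert dm.values.loc["g1", "b"] == 0.0  # included, variant-free
        assert np.isnan(dm.values.loc["g2", "b"])
        assert dm.markers.loc["g2", "b"] == "duplication"

    def test_unknown_gene_in_ordering_raises(self):
        parsed = make_parsed(["g1"], ["a"])
        ann = pd.DataFrame([], columns=ANNOT_COLUMNS)
        with pytest.raises(ValueError):
            density_matrix(parsed, ann, {"g1": 900}, ["g1", "ghost"])


class TestSubfamilyDensity:
    def _evidence(self, genes, strains, length=1000):
        from vrvar.repertoire_qc import SiteEvidence
        return {(g, s): SiteEvidence(g, s, length) for g in genes for s in strains}

    def test_single_strain_single_gene(self):
        parsed = make_parsed(["g1"], ["a"])
        ann = pd.DataFrame([ann_row("g1", "a", p) for p in (3, 9)],
                           columns=ANNOT_COLUMNS)
        out = subfamily_density(parsed, ann, self._evidence(["g1"], ["a"]),
                                {"g1": 1000}, {"g1": "V1R"}, {"pool": ["a"]})
        assert out.mean_nonsyn_per_kb.iloc[0] == pytest.approx(2.0)

    def test_identical_strains_have_zero_pool_variance(self):
        parsed = make_parsed(["g1"], ["a", "b"])
        ann = pd.DataFrame([ann_row("g1", s, 3) for s in "ab"],
                           columns=ANNOT_COLUMNS)
        out = subfamily_density(parsed, ann, self._evidence(["g1"], ["a", "b"]),
                                {"g1": 1000}, {"g1": "V1R"}, {"pool": ["a", "b"]})
        assert out["sem"].iloc[0] == 0.0

    def test_recovers_planted_rate_within_three_standard_errors(self):
        """Ten strains with SNP counts drawn at 2/kb over 20 one-kb genes."""
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(20)]
        strains = [f"s{i}" for i in range(10)]
        parsed = make_parsed(genes, strains)
        rows = []
        for s in strains:
            for g in genes:
                for k in range(rng.poisson(2.0)):
                    rows.append(ann_row(g, s, int(rng.integers(1, 999)) ,
                                        offset=k))
        ann = pd.DataFrame(rows, columns=ANNOT_COLUMNS)
        out = subfamily_density(parsed, ann, self._evidence(genes, strains),
                                {g: 1000 for g in genes},
                                {g: "V1R" for g in genes}, {"pool": strains})
        row = out.iloc[0]
        # planted-rate sampling error: total count ~ Poisson(10*20*2)
        planted_se = np.sqrt(10 * 20 * 2.0) / (10 * 20)
        assert abs(row["mean_nonsyn_per_kb"] - 2.0) < 3 * planted_se


def test_table1_percentages_recompute_from_printed_counts():
    """Per-strain non-synonymous, private and truncating percentages recompute
    from the printed counts (truncating is a share of non-synonymous SNPs)."""
    from vrvar.variation_stats import percentage
    table = reference_data.strain_table()
    printed_nonsyn = [100.0, 56.9, 56.6, 55.5, 60.1, 54.7, 61.1, 56.5, 57.8,
                      58.4, 55.5, 56.2, 58.9, 56.0, 57.6, 63.0, 56.2]
    printed_private = [100.0, 0.72, 0.25, 5.77, 11.3, 2.25, 0.33, 0.00, 1.20,
                       5.95, 2.11, 3.30, 6.37, 36.0, 40.7, 18.2, 74.4]
    for row, nonsyn_pct, private_pct in zip(
            table.itertuples(index=False), printed_nonsyn, printed_private):
        # within half a printed least-significant digit (plus rounding slack)
        assert abs(percentage(row.nonsyn_snps, row.all_snps) - nonsyn_pct) <= 0.06
        assert abs(100 * row.private_snps / row.all_snps - private_pct) <= 0.06
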