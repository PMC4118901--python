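import numpy as np
import pytest

from genediv.io_core import GeneModel, Region
from genediv.variant_scan import (
    VariantTable,
    call_indels,
    call_snps,
    call_variants,
    classify_sites,
    summarize_variant_regions,
)

from conftest import toy_panel


class TestCallSnps:
    def test_minor_allele_in_one_sample_is_singleton(self):
        rows = ["A" * 5] * 7 + ["AAGAA"]
        vt = classify_sites(call_snps(toy_panel(rows)))
        assert len(vt.variants) == 1
        v = vt.variants[0]
        assert v.position == 3 and v.alleles == ["A", "G"]
        assert v.counts == {"A": 7, "G": 1} and v.site_class == "singleton"

    def test_two_minor_carriers_are_parsimony_informative(self):
        rows = ["A" * 5] * 6 + ["AAGAA"] * 2
        vt = classify_sites(call_snps(toy_panel(rows)))
        assert vt.variants[0].site_class == "parsimony_informative"

    def test_reference_only_difference_is_not_a_variant(self):
        panel = toy_panel(["ACGT", "ACGT", "ACGT"], reference="ACTT")
        assert len(call_snps(panel).variants) == 0

    def test_n_bases_are_missing_not_alleles(self):
        rows = ["ACGT", "ANGT", "ACGA"]
        vt = call_snps(toy_panel(rows))
        assert len(vt.variants) == 1  # only column 4; N never creates a variant
        v = vt.variants[0]
        assert v.position == 4 and v.n_missing == 0
        vt2 = call_snps(toy_panel(["AAGT", "ANGT", "ACGT"]))
        assert vt2.variants[0].counts == {"A": 1, "C": 1} or vt2.variants[0].counts == {"C": 1, "A": 1}
        assert vt2.variants[0].n_missing == 1

    def test_gap_columns_excluded_from_snp_calling(self):
        rows = ["ACGT", "A-GT", "ATGT"]
        vt = call_snps(toy_panel(rows))
        assert len(vt.variants) == 0  # polymorphic column 2 is a gap column

    def test_monomorphic_alignment_gives_empty_table(self):
        assert len(call_snps(toy_panel(["ACGT"] * 4)).variants) == 0


class TestCallIndels:
    def test_single_sample_gap_run(self):
        rows = ["ACGTACGT", "AC---CGT", "ACGTACGT"]
        vt = classify_sites(call_indels(toy_panel(rows)))
        assert len(vt.variants) == 1
        v = vt.variants[0]
        assert v.position == 3 and v.span == 3 and v.site_class == "singleton"

    def test_nested_deletions_form_one_triallelic_event(self):
        rows = ["AACGTCGGA", "AA------A", "AACGT---A", "AACGTCGGA"]
        vt = call_indels(toy_panel(rows))
        assert len(vt.variants) == 1
        v = vt.variants[0]
        assert v.span == 6 and len(v.alleles) == 3
        assert sorted(v.allele_lengths.values()) == [0, 3, 6]

    def test_separated_runs_are_separate_events(self):
        rows = ["ACGTACGT", "A-GTAC-T", "ACGTACGT"]
        vt = call_indels(toy_panel(rows))
        assert [v.position for v in vt.variants] == [2, 7]


class TestClassification:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_count_rule_on_small_tables(self, seed):
        """Singleton iff exactly one sample carries a non-major allele,
        checked against direct counting on random tables with N <= 6."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        rows = ["".join(rng.choice(list("ACGT"), 8)) for _ in range(n)]
        vt = classify_sites(call_snps(toy_panel(rows)))
        for v in vt.variants:
            minor = sum(c for a, c in v.counts.items() if a != v.alleles[0])
            assert (v.site_class == "singleton") == (minor == 1)


class TestCodingEffect:
    model = GeneModel([Region("e", "exon", 1, 9)], ["e"])

    def test_third_position_alanine_change_is_synonymous(self):
        rows = ["ATGGCAACC"] * 3 + ["ATGGCGACC"]
        vt = call_variants(toy_panel(rows), self.model)
        assert vt.variants[0].coding_effect == "synonymous"

    def test_second_position_change_is_nonsynonymous(self):
        rows = ["ATGGCAACC"] * 3 + ["ATGGTAACC"]
        vt = call_variants(toy_panel(rows), self.model)
        assert vt.variants[0].coding_effect == "nonsynonymous"

    def test_three_bp_deletion_is_inframe(self):
        rows = ["ATGGCAACC"] * 3 + ["ATG---ACC"]
        vt = call_variants(toy_panel(rows), self.model)
        assert vt.indels()[0].coding_effect == "inframe_del"

    def test_four_bp_deletion_is_frameshift(self):
        rows = ["ATGGCAACCACC"] * 3 + ["ATG----CCACC"]
        vt = call_variants(toy_panel(rows), GeneModel([Region("e", "exon", 1, 12)], ["e"]))
        assert vt.indels()[0].coding_effect == "frameshift"

    def test_noncoding_variant_labelled(self):
        model = GeneModel([Region("p", "promoter", 1, 3), Region("e", "exon", 4, 9)], ["e"])
        rows = ["TTTATGGCA"] * 3 + ["TATATGGCA"]
        vt = call_variants(toy_panel(rows), model)
        assert vt.variants[0].coding_effect == "noncoding"


class TestGeneratorGroundTruth:
    def test_planted_snps_recovered_exactly(self, variants, truth):
        called = {v.position: v for v in variants.snps()}
        assert len(called) == 22
        for snp in truth["snps"]:
            v = called[snp["position"]]
            assert set(v.alleles) == {snp["ref"], snp["alt"]}
            carriers = {s for s, g in zip(variants.sample_ids, v.genotypes) if g == snp["alt"]}
            assert carriers == set(snp["carriers"])

    def test_planted_indels_recovered_exactly(self, variants, truth):
        called = {v.position: v for v in variants.indels()}
        assert len(called) == 8
        for ev in truth["indels"]:
            v = called[ev["start"]]
            assert v.span == ev["span"]
            assert len(v.alleles) == len(ev["alleles"]) + 1

    def test_region_bookkeeping_matches_study_pattern(self, variants, cfg):
        df = summarize_variant_regions(variants, cfg.model).set_index("region")
        assert df.loc["entire", "n_snps"] == 22
        assert list(df["n_snps"][:-1]) == [7, 5, 0, 0, 0, 4, 6]
        assert list(df["n_indel_events"][:-1]) == [1, 1, 3, 0, 1, 1, 1]
        assert list(df["n_indel_sites"][:-1]) == [1, 3, 19, 0, 7, 6, 1]
        assert df.loc["entire", "mean_indel_length"] == pytest.approx(4.625)
        assert df.loc["intron1", "mean_indel_length"] == pytest.approx(6.3333, abs=1e-4)

    def test_partition_property_per_region(self, variants, cfg):
        df = summarize_variant_regions(variants, cfg.model)
        assert (df["n_variants"] == df["n_snps"] + df["n_indel_events"]).all()

    def test_calling_is_permutation_invariant(self, panel, cfg):
        from genediv.io_core import AlignedPanel

        rng = np.random.default_rng(3)
        perm = rng.permutation(panel.n_samples)
        shuffled = AlignedPanel([panel.sample_ids[i] for i in perm], panel.rows[perm],
                                panel.reference_id, panel.reference_seq)
        a = call_variants(panel, cfg.model)
        b = call_variants(shuffled, cfg.model)
        for va, vb in zip(a.variants, b.variants):
            assert (va.position, va.span, va.counts, va.site_class) == \
                   (vb.position, vb.span, vb.counts, vb.site_class)


def test_variant_table_tsv_roundtrip(variants, tmp_path):
    f = tmp_path / "variants.tsv"
    variants.write(f)
    back = VariantTable.read(f)
    assert back.sample_ids == variants.sample_ids
    for va, vb in zip(variants.variants, back.variants):
        assert va.id == vb.id and va.alleles == vb.alleles
        assert list(va.genotypes) == list(vb.genotypes)
        assert (va.region, va.site_class, va.coding_effect) == (vb.region, vb.site_class, vb.coding_effect)
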