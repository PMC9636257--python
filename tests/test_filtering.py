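"""Retention cascade: rule application, artifact merging, contaminants."""

import pytest

from helpers import (
    brute_contaminants,
    brute_filter,
    brute_merge,
    make_table,
    random_filter_table,
)
from sedapipe.filtering import (
    FilterParams,
    curate_mammals,
    filter_barcodes,
    is_homopolymer_variant,
    merge_artifacts,
    remove_contaminants,
    run_cascade,
)
from sedapipe.io_formats import ValidationError

UNITS = {"S1": ("sample", 10, 160), "S2": ("sample", 20, 320), "N1": "extraction_control"}


def one_barcode(counts, identity=1.0, seq="ACGTACGTAC"):
    return make_table(
        [{"id": "b1", "sequence": seq, "identity": identity, "counts": counts}], UNITS
    )


class TestFilterBarcodes:
    def test_reads_5_4_3_retained(self):
        t = one_barcode({"S1": [5, 4, 3]})
        out, rep = filter_barcodes(t)
        assert list(out.meta.index) == ["b1"]
        assert rep.rule_counts == {}

    def test_imperfect_identity_removed_regardless_of_counts(self):
        t = one_barcode({"S1": [500, 400, 300]}, identity=0.98)
        out, rep = filter_barcodes(t)
        assert len(out.meta) == 0
        assert rep.removed["low_identity"] == ["b1"]

    def test_two_reads_everywhere_removed(self):
        t = one_barcode({"S1": [2] * 8, "S2": [2] * 8, "N1": [2] * 4})
        out, rep = filter_barcodes(t)
        assert len(out.meta) == 0
        assert rep.removed["too_few_replicates"] == ["b1"]

    def test_short_sequence_removed(self):
        t = one_barcode({"S1": [5, 4, 3]}, seq="ACGTA")
        out, rep = filter_barcodes(t)
        assert rep.removed["short_sequence"] == ["b1"]

    def test_subthreshold_cells_zeroed_in_retained_table(self):
        t = one_barcode({"S1": [5, 4, 3, 2, 1]})
        out, rep = filter_barcodes(t)
        assert out.counts.loc["b1"].tolist()[:5] == [5, 4, 3, 0, 0]
        assert rep.zeroed_reads == 3

    def test_read_conservation(self, rng):
        for _ in range(10):
            t = random_filter_table(rng, max_barcodes=20)
            _, rep = filter_barcodes(t)
            rep.check_conservation()

    def test_order_robustness(self, rng):
        t = random_filter_table(rng, max_barcodes=15)
        perm = rng.permutation(len(t.meta))
        shuffled = t.subset_barcodes(t.meta.index[perm])
        out1, _ = filter_barcodes(t)
        out2, _ = filter_barcodes(shuffled)
        assert set(out1.meta.index) == set(out2.meta.index)

    def test_matches_brute_force(self, rng):
        params = FilterParams()
        for _ in range(25):
            t = random_filter_table(rng)
            expect_ids, expect_zeroed = brute_filter(t, params)
            out, _ = filter_barcodes(t, params)
            assert list(out.meta.index) == expect_ids
            assert out.counts.equals(expect_zeroed.astype(out.counts.dtypes.iloc[0]))


class TestMergeArtifacts:
    def make(self, seq_counts):
        barcodes = [
            {"id": f"b{i}", "sequence": s, "counts": {"S1": [c]}}
            for i, (s, c) in enumerate(seq_counts)
        ]
        return make_table(barcodes, {"S1": ("sample", 10, 160)})

    def test_homopolymer_variant_merged_into_source(self):
        t = self.make([("AAATG", 1000), ("AAAATG", 10)])
        out, rep = merge_artifacts(t)
        assert list(out.meta.index) == ["b0"]
        assert int(out.total_reads().iloc[0]) == 1010
        assert rep.merged == {"b1": "b0"}

    def test_substitution_not_merged(self):
        t = self.make([("AAATG", 1000), ("AACTG", 10)])
        out, rep = merge_artifacts(t)
        assert len(out.meta) == 2 and rep.merged == {}

    def test_chain_collapses_to_most_abundant(self):
        t = self.make([("AAAT", 5), ("AAAAT", 500), ("AAAAAT", 50)])
        out, rep = merge_artifacts(t)
        assert list(out.meta.index) == ["b1"]
        assert int(out.total_reads().iloc[0]) == 555
        assert rep.merged == {"b0": "b1", "b2": "b1"}

    def test_equal_abundance_never_merges(self):
        t = self.make([("AAATG", 100), ("AAAATG", 100)])
        out, _ = merge_artifacts(t)
        assert len(out.meta) == 2

    def test_variant_predicate(self):
        assert is_homopolymer_variant("AAATG", "AAAATG")
        assert is_homopolymer_variant("AAATG", "AAAAATG")  # any length difference
        assert not is_homopolymer_variant("AAATG", "AAATG")
        assert not is_homopolymer_variant("AAATG", "AACTG")
        assert not is_homopolymer_variant("AATTG", "AAATTTG")  # two runs changed

    def test_matches_brute_force(self, rng):
        for _ in range(25):
            t = random_filter_table(rng, max_barcodes=20)
            expect = brute_merge(t)
            _, rep = merge_artifacts(t)
            assert rep.merged == expect


class TestRemoveContaminants:
    def test_control_enriched_removed(self):
        t = make_table(
            [{"id": "b1", "sequence": "ACGTACGTAC",
              "counts": {"S1": [5], "S2": [5], "N1": [50]}}],
            UNITS,
        )
        out, rep = remove_contaminants(t)
        assert rep.removed["contaminant"] == ["b1"]

    def test_whitelisted_taxon_retained_and_logged(self):
        t = make_table(
            [{"id": "b1", "sequence": "ACGTACGTAC", "taxon": "Picea abies",
              "counts": {"S1": [5], "S2": [5], "N1": [50]}}],
            UNITS,
        )
        out, rep = remove_contaminants(t, FilterParams(whitelist={"Picea abies"}))
        assert list(out.meta.index) == ["b1"]
        assert any("Picea abies" in n for n in rep.notes)
        assert "Picea abies" in rep.control_detected_taxa

    def test_absent_from_controls_retained(self):
        t = make_table(
            [{"id": "b1", "sequence": "ACGTACGTAC",
              "counts": {"S1": [50], "S2": [50], "N1": [0]}}],
            UNITS,
        )
        out, _ = remove_contaminants(t)
        assert list(out.meta.index) == ["b1"]

    def test_blacklist_always_removed(self):
        t = make_table(
            [{"id": "b1", "sequence": "ACGTACGTAC", "taxon": "Zea mays",
              "counts": {"S1": [500], "N1": [0]}}],
            UNITS,
        )
        _, rep = remove_contaminants(t, FilterParams(blacklist={"Zea mays"}))
        assert rep.removed["blacklisted"] == ["b1"]

    def test_no_controls_is_error(self):
        t = make_table(
            [{"id": "b1", "sequence": "ACGTACGTAC", "counts": {"S1": [5]}}],
            {"S1": ("sample", 10, 160)},
        )
        with pytest.raises(ValidationError, match="control"):
            remove_contaminants(t)

    def test_matches_brute_force(self, rng):
        for _ in range(25):
            t = random_filter_table(rng)
            _, rep = remove_contaminants(t)
            assert sorted(rep.removed.get("contaminant", [])) == sorted(brute_contaminants(t))


class TestCurateMammals:
    UNITS_M = {
        "S1": ("sample", 10, 160),
        "S2": ("sample", 20, 320),
        "S3": ("sample", 30, 480),
        "N1": "pcr_control",
    }

    def mammal_table(self):
        barcodes = [
            {"id": "m1", "sequence": "ACGTACGTACGT", "taxon": "Ovis aries",
             "counts": {"S1": [10, 8, 0, 0], "S2": [6, 0, 0, 0]}},
            {"id": "m2", "sequence": "ACGTACGTACGA", "taxon": "Ovis aries",
             "counts": {"S1": [3, 0, 0, 0]}},
            {"id": "m3", "sequence": "TTGCATTGCAGG", "taxon": "Homo sapiens",
             "counts": {"S1": [100, 100, 100, 100]}},
            {"id": "m4", "sequence": "GGCATGGCATAA", "taxon": "Bos taurus",
             "counts": {"S2": [4, 0, 0, 0]}},
        ]
        return make_table(barcodes, self.UNITS_M, category="mammal_16S")

    def test_collapse_by_taxon(self):
        out, rep, _ = curate_mammals(self.mammal_table())
        taxa = sorted(out.meta["taxon"])
        assert taxa == ["Bos taurus", "Ovis aries"]
        sheep = out.meta.index[out.meta["taxon"] == "Ovis aries"][0]
        assert int(out.total_reads()[sheep]) == 10 + 8 + 6 + 3

    def test_discard_human(self):
        _, rep, _ = curate_mammals(self.mammal_table())
        assert rep.removed["discarded_taxon"] == ["m3"]

    def test_sporadic_single_isolated_detection_flagged(self):
        # cow: one replicate of one sample, sheep absent in adjacent -> sporadic
        _, _, sporadic = curate_mammals(self.mammal_table())
        assert ("Bos taurus", "S2") in set(zip(sporadic["taxon"], sporadic["sample_id"]))
        # sheep in S1 has 3 detections (10, 8 and merged 3) -> not sporadic
        assert "Ovis aries" not in set(sporadic["taxon"][sporadic["sample_id"] == "S1"])

    def test_detection_in_adjacent_sample_is_not_sporadic(self):
        barcodes = [
            {"id": "m1", "sequence": "ACGTACGTACGT", "taxon": "Capra hircus",
             "counts": {"S1": [5, 0, 0, 0], "S2": [4, 0, 0, 0]}},
        ]
        t = make_table(barcodes, self.UNITS_M, category="mammal_16S")
        _, _, sporadic = curate_mammals(t)
        assert sporadic.empty

    def test_wrong_category_is_error(self):
        t = make_table(
            [{"id": "b1", "sequence": "ACGTACGTAC", "counts": {"S1": [5]}}],
            {"S1": ("sample", 10, 160)},
        )
        with pytest.raises(ValidationError, match="mammal"):
            curate_mammals(t)


class TestCascadeOnSyntheticTruth:
    def test_injected_structure_recovered(self, small_community, small_retained):
        table, _, truth = small_community
        retained, reports = small_retained
        merged = reports[1].merged
        removed_contaminant = set(reports[3].removed.get("contaminant", []))
        # every injected contaminant removed
        assert set(truth.contaminant_ids) <= removed_contaminant
        # every injected artifact merged into its true source
        assert merged == truth.artifact_sources
        # no genuine perfect-identity taxon lost
        genuine = {
            b for b in truth.true_abundance.columns if b not in truth.low_identity_ids
        }
        assert genuine <= set(retained.meta.index)
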