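import numpy as np
import pandas as pd
import pytest

from snvlink.consensus import (
    ConsensusParams,
    GRNARecord,
    assign_consequence,
    call_consensus,
    compare_to_prediction,
    filter_edit_types,
    map_puror_to_grna_ibar,
    form_barcode_groups,
    predict_genotype_from_grna,
    remove_recurrent_artifacts,
)
from snvlink.containers import BarcodeGroup, ConsensusGenotype, VARIANT_COLUMNS

from oracles import consensus_oracle

PARAMS = ConsensusParams(promoter_interval=("chr1", 500, 1000))


def variant_table(rows):
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def co_frame(rows):
    """rows: (cell, grna, ibar, puror)."""
    df = pd.DataFrame(rows, columns=["cell_id", "grna", "ibar", "puror"])
    df["unique_grna_ibar"] = (df["grna"] != "") & (df["ibar"] != "")
    df["unique_puror"] = df["puror"] != ""
    df["both"] = df["unique_grna_ibar"] & df["unique_puror"]
    return df


class TestPurorMapping:
    def test_unique_pairing_with_enough_cells_maps(self):
        co = co_frame([(f"c{i}", "g1", "i1", "P1") for i in range(5)])
        assert map_puror_to_grna_ibar(co) == {"P1": ("g1", "i1")}

    def test_single_cell_pairing_unmapped(self):
        co = co_frame([("c1", "g1", "i1", "P2")])
        assert map_puror_to_grna_ibar(co) == {}

    def test_ambiguous_pairing_unmapped(self):
        co = co_frame(
            [("c1", "g1", "i1", "P3"), ("c2", "g1", "i1", "P3"),
             ("c3", "g2", "i2", "P3"), ("c4", "g2", "i2", "P3")]
        )
        assert map_puror_to_grna_ibar(co) == {}


class TestFormGroups:
    def test_partial_barcodes_join_through_mapping(self):
        rows = [(f"c{i}", "g1", "i1", "P1") for i in range(4)]
        rows += [(f"d{i}", "g1", "i1", "") for i in range(2)]
        rows += [("e0", "", "", "P1")]
        groups, excluded = form_barcode_groups(
            co_frame(rows), {"P1": ("g1", "i1")}
        )
        assert len(groups) == 1 and groups[0].size == 7
        assert excluded.empty

    def test_conflicting_keys_excluded(self):
        rows = [("c1", "g1", "i1", "P9")]
        groups, excluded = form_barcode_groups(
            co_frame(rows), {"P9": ("g2", "i2")}
        )
        assert not groups
        assert list(excluded["reason"]) == ["conflicting_barcodes"]

    def test_no_cells(self):
        groups, excluded = form_barcode_groups(co_frame([]), {})
        assert groups == []


class TestEditTypeFilter:
    def test_filter_matches_set_membership_oracle(self):
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        rows = []
        for i in range(200):
            ref, alt = rng.choice(bases, size=2, replace=False)
            rows.append((f"c{i}", "chr1", int(rng.integers(1, 999)), ref, alt, 1))
        table = variant_table(rows)
        out = filter_edit_types(table, PARAMS)
        expect = table[
            [(r, a) in {("C", "T"), ("G", "A")}
             for r, a in zip(table["ref"], table["alt"])]
        ]
        pd.testing.assert_frame_equal(
            out.reset_index(drop=True), expect.reset_index(drop=True)
        )

    def test_malformed_rows_rejected_with_warning(self):
        table = variant_table(
            [("c1", "chr1", 5, "C", "C", 1), ("c2", "chr1", 6, "C", "T", 1)]
        )
        with pytest.warns(RuntimeWarning, match="malformed"):
            out = filter_edit_types(table, PARAMS)
        assert len(out) == 1


class TestRecurrenceFilter:
    def test_strictly_above_ten_percent_removed(self):
        groups = [f"b{i}" for i in range(233)]
        incidence = {
            "frequent": set(groups[:30]),     # 12.9% -> removed
            "rare": set(groups[:5]),          # kept
            "boundary": set(groups[:23]),     # 23/233 = 9.87% -> kept
        }
        kept = remove_recurrent_artifacts(incidence, n_groups=233)
        assert kept == {"rare", "boundary"}

    def test_exactly_at_cutoff_kept(self):
        incidence = {"v": {f"b{i}" for i in range(10)}}
        assert remove_recurrent_artifacts(incidence, n_groups=100) == {"v"}

    def test_zero_groups_error(self):
        with pytest.raises(ValueError):
            remove_recurrent_artifacts({}, n_groups=0)


class TestCallConsensus:
    @staticmethod
    def _call(n, carrier_dosages, pos=100):
        group = BarcodeGroup("G", [f"c{i}" for i in range(n)], ("g", "i"))
        rows = [
            (f"c{i}", "chr1", pos, "C", "T", d)
            for i, d in enumerate(carrier_dosages)
        ]
        return call_consensus(group, variant_table(rows), PARAMS)

    def test_homozygous_majority_called(self):
        geno = self._call(5, [3, 3, 3])
        assert geno.status == "edited"
        assert geno.variants == [("chr1", 100, "C", "T", 3)]
        assert geno.zygosity == "homozygous"

    def test_forty_percent_carriers_uncallable(self):
        assert self._call(5, [3, 3]).status == "uncallable"

    def test_large_group_tolerates_one_mutated_cell(self):
        assert self._call(12, [2]).status == "WT"

    def test_clean_group_is_wt(self):
        assert self._call(4, []).status == "WT"

    def test_small_group_never_genotyped(self):
        geno = self._call(2, [3, 3])
        assert geno.status == "uncallable" and geno.reason == "too_few_cells"

    def test_dosage_tie_uncallable(self):
        assert self._call(4, [3, 3, 2, 2]).status == "uncallable"

    def test_matches_brute_force_oracle_on_random_groups(self):
        """1,000 random small groups agree with a plain-loop reimplementation."""
        rng = np.random.default_rng(2024)
        variants = [("chr1", int(p), "C", "T") for p in (10, 20, 30, 40)]
        for _ in range(1000):
            n = int(rng.integers(1, 9))
            cells = {}
            rows = []
            for i in range(n):
                muts = {}
                for v in variants:
                    if rng.random() < 0.35:
                        d = int(rng.integers(1, 4))
                        muts[v] = d
                        rows.append((f"c{i}", *v, d))
                cells[f"c{i}"] = muts
            group = BarcodeGroup("G", [f"c{i}" for i in range(n)], ("g", "i"))
            geno = call_consensus(group, variant_table(rows), PARAMS)
            status, called = consensus_oracle(cells, n)
            assert geno.status == status, (cells, geno)
            if status == "edited":
                assert {
                    (c, p, r, a): d for c, p, r, a, d in geno.variants
                } == called

    def test_invariant_to_cell_and_variant_order(self):
        rng = np.random.default_rng(9)
        rows = [
            (f"c{i}", "chr1", int(p), "C", "T", int(rng.integers(1, 4)))
            for i in range(6)
            for p in rng.choice([10, 20, 30], size=2, replace=False)
        ]
        group = BarcodeGroup("G", [f"c{i}" for i in range(6)], ("g", "i"))
        base = call_consensus(group, variant_table(rows), PARAMS)
        shuffled = variant_table(
            [rows[i] for i in rng.permutation(len(rows))]
        )
        group2 = BarcodeGroup(
            "G", [f"c{i}" for i in rng.permutation(6)], ("g", "i")
        )
        again = call_consensus(group2, shuffled, PARAMS)
        assert base.status == again.status and base.variants == again.variants


class TestConsequence:
    def _genotype(self, variants):
        return ConsensusGenotype("G", "edited", variants=variants, n_cells=5)

    def test_most_severe_homozygous_wins(self):
        geno = self._genotype(
            [("chr1", 10, "C", "T", 3), ("chr1", 20, "C", "T", 3)]
        )
        ann = {("chr1", 10, "C", "T"): "synonymous",
               ("chr1", 20, "C", "T"): "stop_gained"}
        assert assign_consequence(geno, ann, PARAMS).consequence == "stop_gained"

    def test_promoter_interval_needs_no_annotation(self):
        geno = self._genotype([("chr1", 700, "C", "T", 3)])
        assert assign_consequence(geno, {}, PARAMS).consequence == "promoter"

    def test_heterozygous_only_has_no_consequence(self):
        geno = self._genotype([("chr1", 10, "C", "T", 1)])
        ann = {("chr1", 10, "C", "T"): "missense"}
        out = assign_consequence(geno, ann, PARAMS)
        assert out.consequence == "none (heterozygous)"

    def test_unannotated_variant_outside_promoter_raises(self):
        geno = self._genotype([("chr1", 10, "C", "T", 3)])
        with pytest.raises(ValueError, match="unannotated"):
            assign_consequence(geno, {}, PARAMS)


class TestPrediction:
    def test_window_cytosines_predicted_homozygous(self):
        grna = GRNARecord(
            "g1", protospacer="AAACACAAAAAAAAAAAAAA", chrom="chr1",
            start=1000, strand="+",
        )
        pred = predict_genotype_from_grna(grna, window=(4, 8), ploidy=3)
        assert pred.variants == [
            ("chr1", 1003, "C", "T", 3), ("chr1", 1005, "C", "T", 3)
        ]

    def test_reverse_strand_maps_to_forward_g_to_a(self):
        grna = GRNARecord(
            "g2", protospacer="AAAACAAAAAAAAAAAAAAA", chrom="chr1",
            start=1000, strand="-",
        )
        pred = predict_genotype_from_grna(grna)
        assert pred.variants == [("chr1", 996, "G", "A", 3)]

    def test_no_window_c_predicts_wt(self):
        grna = GRNARecord("g3", "A" * 20, chrom="chr1", start=10, strand="+")
        assert predict_genotype_from_grna(grna).variants == []

    def test_non_targeting_flagged(self):
        pred = predict_genotype_from_grna(GRNARecord("nt", "A" * 20, targeting=False))
        assert pred.non_targeting and pred.variants == []

    def test_window_outside_protospacer_raises(self):
        grna = GRNARecord("g4", "ACGT", chrom="chr1", start=10, strand="+")
        with pytest.raises(ValueError, match="window"):
            predict_genotype_from_grna(grna, window=(4, 8))


class TestCompareToPrediction:
    ANN = {("chr1", 1003, "C", "T"): "missense"}

    def _pred(self):
        grna = GRNARecord(
            "g1", "AAACAAAAAAAAAAAAAAAA", chrom="chr1", start=1000, strand="+"
        )
        return predict_genotype_from_grna(grna, annotation=self.ANN)

    def test_identical_call_concordant(self):
        called = ConsensusGenotype(
            "G", "edited", variants=[("chr1", 1003, "C", "T", 3)],
            consequence="missense", n_cells=5,
        )
        rec = compare_to_prediction(called, self._pred(), self.ANN, PARAMS)
        assert rec["nucleotide_match"] and rec["protein_match"]

    def test_heterozygous_call_discordant(self):
        called = ConsensusGenotype(
            "G", "edited", variants=[("chr1", 1003, "C", "T", 1)],
            consequence="none (heterozygous)", n_cells=5,
        )
        rec = compare_to_prediction(called, self._pred(), self.ANN, PARAMS)
        assert not rec["nucleotide_match"]
        assert rec["discordance_reason"] == "heterozygous"

    def test_wt_call_discordant_as_unedited(self):
        called = ConsensusGenotype("G", "WT", consequence="WT", n_cells=5)
        rec = compare_to_prediction(called, self._pred(), self.ANN, PARAMS)
        assert not rec["nucleotide_match"]
        assert rec["discordance_reason"] == "unedited"
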