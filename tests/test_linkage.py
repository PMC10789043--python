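import numpy as np
import pandas as pd
import pytest

from snvlink.containers import ConsensusGenotype
from snvlink.linkage import (
    LinkageSummary,
    concordance_summary,
    evaluate_classification,
    filter_lone_barcode_cells,
    link_rna_to_genotype,
    summarize_linkage,
    transfer_labels,
)

from oracles import knn_transfer_oracle


def co_frame(rows):
    df = pd.DataFrame(rows, columns=["cell_id", "grna", "ibar", "puror"])
    df["unique_grna_ibar"] = (df["grna"] != "") & (df["ibar"] != "")
    df["unique_puror"] = df["puror"] != ""
    df["both"] = df["unique_grna_ibar"] & df["unique_puror"]
    return df


class TestLinkRnaToGenotype:
    CONSENSUS = {
        "g1|i1": ConsensusGenotype("g1|i1", "edited",
                                   variants=[("chr1", 5, "C", "T", 3)],
                                   consequence="missense", n_cells=5),
        "g2|i2": ConsensusGenotype("g2|i2", "uncallable", reason="dosage_tie",
                                   n_cells=4),
    }

    def test_matching_callable_group_links(self):
        linked, unlinked = link_rna_to_genotype(
            co_frame([("r1", "g1", "i1", "")]), self.CONSENSUS, {}
        )
        assert list(linked["group_id"]) == ["g1|i1"]
        assert linked["consequence"].iloc[0] == "missense"

    def test_uncallable_group_reported(self):
        linked, unlinked = link_rna_to_genotype(
            co_frame([("r1", "g2", "i2", "")]), self.CONSENSUS, {}
        )
        assert linked.empty
        assert list(unlinked["reason"]) == ["uncallable_genotype"]

    def test_puror_only_cell_links_through_mapping(self):
        linked, _ = link_rna_to_genotype(
            co_frame([("r1", "", "", "P1")]), self.CONSENSUS,
            {"P1": ("g1", "i1")},
        )
        assert list(linked["group_id"]) == ["g1|i1"]


class TestTransferLabels:
    def test_identical_query_inherits_label_and_coords(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(size=(20, 3))
        ids = [f"r{i}" for i in range(20)]
        labels = {r: ("LoF" if i < 10 else "notLoF") for i, r in enumerate(ids)}
        umap = rng.normal(size=(20, 2))
        out = transfer_labels(ref, ids, labels, ref[[4]], ["q0"],
                              reference_extra_coords=umap, k=1)
        assert out["label"].iloc[0] == labels["r4"]
        assert out[["coord_1", "coord_2"]].iloc[0].tolist() == umap[4].tolist()

    def test_matches_exhaustive_oracle_on_small_fixture(self):
        rng = np.random.default_rng(5)
        ref = rng.normal(size=(12, 2))
        ids = [f"r{i:02d}" for i in range(12)]
        labels = {r: ["A", "B", "C"][i % 3] for i, r in enumerate(ids)}
        query = rng.normal(size=(30, 2))
        out = transfer_labels(ref, ids, labels, query,
                              [f"q{i}" for i in range(30)], k=5)
        expect = knn_transfer_oracle(ref, ids, labels, query, k=5)
        assert list(out["label"]) == expect

    def test_modal_rule_six_of_ten(self):
        # ten reference points at increasing distance; six nearest share a label
        ref = np.arange(10, dtype=float)[:, None]
        ids = [f"r{i}" for i in range(10)]
        labels = {f"r{i}": ("LoF" if i < 6 else "notLoF") for i in range(10)}
        out = transfer_labels(ref, ids, labels, np.array([[-1.0]]), ["q"], k=10)
        assert out["label"].iloc[0] == "LoF"

    def test_k_exceeding_reference_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            transfer_labels(np.zeros((3, 2)), ["a", "b", "c"],
                            {"a": 1, "b": 1, "c": 1}, np.zeros((1, 2)), ["q"],
                            k=10)


class TestFilterLoneBarcodeCells:
    def test_lone_cell_in_cluster_removed(self):
        rows = [("c%d" % i, "b1", "LoF") for i in range(5)]
        rows.append(("c9", "b1", "notLoF"))
        linked = pd.DataFrame(rows, columns=["cell_id", "group_id", "label"])
        out = filter_lone_barcode_cells(linked)
        assert "c9" not in set(out["cell_id"])
        assert len(out) == 5

    def test_pairs_retained(self):
        rows = [("c1", "b1", "LoF"), ("c2", "b1", "LoF"),
                ("c3", "b1", "notLoF"), ("c4", "b1", "notLoF")]
        linked = pd.DataFrame(rows, columns=["cell_id", "group_id", "label"])
        assert len(filter_lone_barcode_cells(linked)) == 4

    def test_matches_brute_force_group_count(self):
        rng = np.random.default_rng(3)
        rows = [
            (f"c{i}", f"b{rng.integers(4)}", ["LoF", "notLoF"][rng.integers(2)])
            for i in range(60)
        ]
        linked = pd.DataFrame(rows, columns=["cell_id", "group_id", "label"])
        out = set(filter_lone_barcode_cells(linked)["cell_id"])
        counts = {}
        for _, b, m in rows:
            counts[(b, m)] = counts.get((b, m), 0) + 1
        expect = {c for c, b, m in rows if counts[(b, m)] > 1}
        assert out == expect


class TestEvaluateClassification:
    @staticmethod
    def _table(stop_lof, stop_not, wt_lof, wt_not, splice_lof=0, splice_not=0):
        rows = (
            [("stop_gained", "LoF")] * stop_lof
            + [("stop_gained", "notLoF")] * stop_not
            + [("splice", "LoF")] * splice_lof
            + [("splice", "notLoF")] * splice_not
            + [("WT", "LoF")] * wt_lof
            + [("WT", "notLoF")] * wt_not
        )
        return pd.DataFrame(rows, columns=["consequence", "phenotype"])

    def test_printed_confusion_counts_give_96_96(self):
        """TP=26, FP=1, FN=1 -> precision and recall both round to 96%."""
        report = evaluate_classification(
            self._table(stop_lof=12, stop_not=0, splice_lof=14, splice_not=1,
                        wt_lof=1, wt_not=76)
        )
        assert (report.tp, report.fp, report.fn) == (26, 1, 1)
        assert report.precision_pct == 96 and report.recall_pct == 96

    def test_zero_positive_class_flags_undefined(self):
        report = evaluate_classification(self._table(0, 0, 2, 10))
        with pytest.raises(ZeroDivisionError):
            _ = report.precision

    def test_random_tables_match_formula(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            counts = rng.integers(0, 6, size=4)
            table = self._table(*counts)
            table = table.sample(frac=1, random_state=1)  # permutation invariant
            r = evaluate_classification(table)
            assert (r.tp, r.fp, r.fn, r.tn) == tuple(counts)
            if r.tp + r.fp:
                assert 0 <= r.precision <= 1


class TestSummarizeLinkage:
    def test_printed_counts_give_77_and_93_percent(self):
        rows = []
        # 10,112 both; 13,102-10,112 puroR-only; 10,869-10,112 gRNA+iBAR-only
        rows += [(f"b{i}", "g", "i", "p") for i in range(10_112)]
        rows += [(f"p{i}", "", "", "p") for i in range(13_102 - 10_112)]
        rows += [(f"g{i}", "g", "i", "") for i in range(10_869 - 10_112)]
        summary = summarize_linkage(co_frame(rows))
        assert summary.n_unique_puror == 13_102
        assert summary.n_unique_grna_ibar == 10_869
        assert summary.pct_puror_with_grna_ibar == 77
        assert summary.pct_grna_ibar_with_puror == 93

    def test_full_overlap_is_100(self):
        summary = LinkageSummary(5, 5, 5)
        assert summary.pct_puror_with_grna_ibar == 100
        assert summary.pct_grna_ibar_with_puror == 100

    def test_zero_cells_raise(self):
        with pytest.raises(ValueError):
            summarize_linkage(co_frame([]))

    def test_random_fixture_matches_set_oracle(self):
        rng = np.random.default_rng(2)
        rows = []
        for i in range(100):
            has_gi = rng.random() < 0.7
            has_p = rng.random() < 0.7
            rows.append(
                (f"c{i}", "g" if has_gi else "", "i" if has_gi else "",
                 "p" if has_p else "")
            )
        co = co_frame(rows)
        s = summarize_linkage(co)
        gi = {r[0] for r in rows if r[1]}
        pu = {r[0] for r in rows if r[3]}
        assert s.n_both == len(gi & pu)
        assert s.n_unique_grna_ibar == len(gi)
        assert s.n_unique_puror == len(pu)


class TestConcordanceSummary:
    @staticmethod
    def _rec(nuc, prot, reason=None):
        return {
            "nucleotide_match": nuc, "protein_match": prot,
            "discordance_reason": reason,
        }

    def test_all_concordant_is_100(self):
        out = concordance_summary([self._rec(True, True)] * 4)
        assert out["pct_nucleotide_concordant"] == 100
        assert out["pct_protein_concordant"] == 100
        assert out["discordance_breakdown"] == {}

    def test_breakdown_fractions(self):
        records = (
            [self._rec(True, True)] * 5
            + [self._rec(False, False, "heterozygous")] * 3
            + [self._rec(False, False, "unedited")] * 2
        )
        out = concordance_summary(records)
        assert out["fraction_protein_concordant"] == 0.5
        assert out["discordance_breakdown"]["heterozygous"] == pytest.approx(0.6)

    def test_empty_records_raise(self):
        with pytest.raises(ValueError):
            concordance_summary([])
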