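import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from snvlink.containers import CountMatrix
from snvlink.simulate import generate_screen
from snvlink.transcriptome import (
    AnalysisParams,
    Embedding,
    ClusterResult,
    bimodality_coefficient,
    classify_barcodes,
    cluster_and_merge,
    de_auc,
    de_auc_cells,
    diffusion_score,
    lof_group_de,
    qc_filter,
    select_features_and_embed,
    sof_gene_signature,
)

from conftest import small_config
from oracles import auc_oracle


def gene_matrix(dense, cell_ids=None):
    dense = np.asarray(dense)
    n, m = dense.shape
    return CountMatrix(
        sp.csr_matrix(dense),
        cell_ids or [f"c{i}" for i in range(n)],
        [f"g{j}" for j in range(m)],
        ["gene"] * m,
    )


@pytest.fixture(scope="module")
def embedded_screen():
    """Small two-state screen taken through embedding and scoring."""
    cfg = small_config(
        n_barcodes=30, cells_per_barcode_rna=20, n_genes=250,
        n_signature_genes=25, frac_nt=0.2, seed=23,
    )
    truth, _, expr, _, _ = generate_screen(cfg)
    cell_grna = {}
    lib = truth.barcodes.set_index("barcode_id")
    for cell_id, barcode_id in truth.cells_rna[
        ["cell_id", "barcode_id"]
    ].itertuples(index=False):
        cell_grna[cell_id] = lib.loc[barcode_id, "grna_id"]
    nt = set(
        truth.grna_library.loc[~truth.grna_library["targeting"], "grna_id"]
    )
    emb = select_features_and_embed(
        expr, cell_grna, nt, truth.signature_genes, seed=0
    )
    return truth, expr, cell_grna, nt, emb


class TestQCFilter:
    def test_homogeneous_matrix_keeps_every_cell(self):
        counts = np.tile([5, 3, 0, 7], (40, 1))
        filtered, report = qc_filter(gene_matrix(counts))
        assert report["n_kept"] == 40

    def test_planted_low_count_outliers_removed(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(20, size=(200, 50))
        counts[:2] = rng.poisson(1, size=(2, 50))  # planted 1% outliers
        filtered, report = qc_filter(gene_matrix(counts))
        kept = set(filtered.cell_ids)
        assert "c0" not in kept and "c1" not in kept
        assert report["n_kept"] >= 190

    def test_empty_mito_set_vacuous(self):
        counts = np.tile([5, 3, 2, 7], (30, 1))
        _, report = qc_filter(gene_matrix(counts), mito_mask=np.zeros(4, bool))
        assert report["removed_high_mito"] == 0

    def test_all_cells_removed_raises(self):
        # with a negative multiplier the low-outlier cut sits above every
        # cell's total, so the guard against an empty matrix must fire
        counts = np.diag([0, 2, 3, 4]) + np.zeros((4, 4), dtype=int)
        with pytest.raises(ValueError, match="every cell"):
            qc_filter(gene_matrix(counts), mad_multiplier=-3)


class TestDeAuc:
    def test_small_example_matches_exhaustive_pairs(self):
        a, b = np.array([1.0, 2.0, 2.0]), np.array([2.0, 3.0])
        res = de_auc(a, b, ["g0"])
        assert res["auc"].iloc[0] == pytest.approx(auc_oracle(a, b))
        # six pairs: two ties at 1/2 each, no wins -> AUC = 1/6
        assert res["auc"].iloc[0] == pytest.approx(1.0 / 6)

    def test_complete_separation_gives_auc_one(self):
        res = de_auc(np.array([5.0, 6.0]), np.array([1.0, 2.0]), ["g0"])
        assert res["auc"].iloc[0] == 1.0
        assert res["direction"].iloc[0] == "up"

    def test_random_vectors_match_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            a = rng.integers(0, 5, size=rng.integers(2, 10)).astype(float)
            b = rng.integers(0, 5, size=rng.integers(2, 10)).astype(float)
            res = de_auc(a, b, ["g"])
            assert res["auc"].iloc[0] == pytest.approx(auc_oracle(a, b))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_antisymmetry(self, seed):
        """AUC(A vs B) + AUC(B vs A) = 1 per gene, ties included."""
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 4, size=(8, 5)).astype(float)
        b = rng.integers(0, 4, size=(6, 5)).astype(float)
        ab = de_auc(a, b, list("vwxyz"))["auc"].to_numpy()
        ba = de_auc(b, a, list("vwxyz"))["auc"].to_numpy()
        assert np.allclose(ab + ba, 1.0)

    def test_qvalues_bound_pvalues(self):
        rng = np.random.default_rng(5)
        res = de_auc(rng.normal(size=(20, 40)), rng.normal(size=(20, 40)),
                     [f"g{i}" for i in range(40)])
        assert (res["qval"] >= res["pval"]).all()

    def test_overlapping_groups_raise(self):
        expr = np.arange(12, dtype=float).reshape(6, 2)
        with pytest.raises(ValueError, match="overlap"):
            de_auc_cells(expr, [f"c{i}" for i in range(6)],
                         ["c0", "c1"], ["c1", "c2"], ["g0", "g1"])


class TestEmbedding:
    def test_top_pc_separates_states(self, embedded_screen):
        truth, expr, _, _, emb = embedded_screen
        states = truth.cells_rna.set_index("cell_id")["state"]
        lof = np.array([states[c] == "lof" for c in emb.cell_ids])
        auc = auc_oracle(emb.coords[lof, 0][:200], emb.coords[~lof, 0][:200])
        assert max(auc, 1 - auc) >= 0.95

    def test_no_de_genes_falls_back_to_pathway(self):
        rng = np.random.default_rng(4)
        expr = gene_matrix(rng.poisson(5, size=(60, 30)))
        cell_grna = {f"c{i}": ("NT1" if i % 2 else "g1") for i in range(60)}
        emb = select_features_and_embed(
            expr, cell_grna, {"NT1"}, ["g0", "g1", "g2"],
            params=AnalysisParams(n_pcs=2), seed=0,
        )
        assert emb.genes == ["g0", "g1", "g2"]

    def test_small_grnas_excluded_from_discovery(self):
        """A gRNA with fewer than 10 cells contributes no DE genes."""
        rng = np.random.default_rng(8)
        base = rng.poisson(5, size=(69, 20))
        base[60:, 0] = 200  # 9 cells with a huge shift in g0
        expr = gene_matrix(base)
        cell_grna = {f"c{i}": "NT1" for i in range(60)}
        cell_grna.update({f"c{i}": "gBig" for i in range(60, 69)})
        emb = select_features_and_embed(
            expr, cell_grna, {"NT1"}, ["g5"],
            params=AnalysisParams(n_pcs=2), seed=0,
        )
        assert emb.genes == ["g5"]

    def test_empty_union_raises(self):
        rng = np.random.default_rng(4)
        expr = gene_matrix(rng.poisson(5, size=(40, 10)))
        cell_grna = {f"c{i}": "NT1" for i in range(40)}
        with pytest.raises(ValueError, match="union"):
            select_features_and_embed(expr, cell_grna, {"NT1"}, [], seed=0)


class TestClusterAndMerge:
    def _two_blob_embedding(self, n=120, seed=0, shift=8.0):
        rng = np.random.default_rng(seed)
        coords = rng.normal(size=(n, 4))
        coords[: n // 2, 0] += shift
        return Embedding(
            coords=coords,
            cell_ids=np.array([f"c{i:03d}" for i in range(n)], dtype=object),
            genes=["g"],
        )

    def test_recovers_two_states(self):
        emb = self._two_blob_embedding()
        nt = {f"c{i:03d}": i >= 60 for i in range(120)}
        result = cluster_and_merge(emb, nt)
        labels = result.table.set_index("cell_id")["meta"]
        truth = ["LoF" if i < 60 else "notLoF" for i in range(120)]
        got = [labels[f"c{i:03d}"] for i in range(120)]
        assert adjusted_rand_score(truth, got) >= 0.99
        # NT-rich side is labelled notLoF
        assert labels["c100"] == "notLoF"

    def test_exactly_two_meta_clusters(self):
        emb = self._two_blob_embedding(seed=5)
        nt = {f"c{i:03d}": i >= 60 for i in range(120)}
        result = cluster_and_merge(emb, nt)
        assert set(result.table["meta"]) == {"LoF", "notLoF"}

    def test_partition_invariant_to_cell_order(self):
        emb = self._two_blob_embedding(seed=2)
        nt = {f"c{i:03d}": i >= 60 for i in range(120)}
        base = cluster_and_merge(emb, nt).table.set_index("cell_id")["meta"]
        perm = np.random.default_rng(1).permutation(120)
        emb2 = Embedding(
            coords=emb.coords[perm], cell_ids=emb.cell_ids[perm], genes=["g"]
        )
        again = cluster_and_merge(emb2, nt).table.set_index("cell_id")["meta"]
        assert (base.sort_index() == again.sort_index()).all()

    def test_too_few_cells_raise(self):
        emb = self._two_blob_embedding(n=12)
        with pytest.raises(ValueError, match="at least"):
            cluster_and_merge(emb, {})


class TestDiffusionScore:
    def _embedding(self, n=150, seed=0):
        rng = np.random.default_rng(seed)
        t = rng.uniform(0, 1, size=n)  # latent trajectory
        coords = np.c_[5 * t, np.zeros(n)] + rng.normal(scale=0.3, size=(n, 2))
        cells = np.array([f"c{i:03d}" for i in range(n)], dtype=object)
        return Embedding(coords=coords, cell_ids=cells, genes=["g"]), t

    def test_orientation_and_correlation_with_latent_state(self):
        emb, t = self._embedding()
        ref = [c for c, ti in zip(emb.cell_ids, t) if ti < 0.2]
        result = diffusion_score(emb, ref)
        scores = result.scores[emb.cell_ids].to_numpy()
        r = np.corrcoef(scores, t)[0, 1]
        assert r >= 0.95
        assert scores.min() == 0.0 and scores.max() == 1.0
        assert result.scores[ref].mean() < result.scores.mean()

    def test_duplicated_cells_share_scores(self):
        emb, t = self._embedding(n=60, seed=3)
        dup = Embedding(
            coords=np.vstack([emb.coords, emb.coords]),
            cell_ids=np.array(
                list(emb.cell_ids) + [f"{c}_dup" for c in emb.cell_ids],
                dtype=object,
            ),
            genes=["g"],
        )
        ref = list(emb.cell_ids[:5])
        scores = diffusion_score(dup, ref).scores
        for c in emb.cell_ids:
            assert scores[c] == pytest.approx(scores[f"{c}_dup"], abs=1e-6)

    def test_disconnected_graph_raises(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(60, 2))
        coords[30:, 0] += 1e4
        emb = Embedding(
            coords=coords,
            cell_ids=np.array([f"c{i}" for i in range(60)], dtype=object),
            genes=["g"],
        )
        with pytest.raises(ValueError, match="connected"):
            diffusion_score(emb, [emb.cell_ids[0]])


class TestClassifyBarcodes:
    def _scores(self, means, n=30, spread=0.01, seed=0):
        rng = np.random.default_rng(seed)
        cells, vals, mapping = [], [], {}
        for b, mu in means.items():
            for i in range(n):
                cid = f"{b}_{i}"
                cells.append(cid)
                vals.append(np.clip(rng.normal(mu, spread), 0, 1))
                mapping[cid] = b
        return pd.Series(vals, index=cells), mapping

    def test_reference_anchored_classes(self):
        means = {"wt1": 0.02, "wt2": 0.05, "stop1": 0.95, "stop2": 0.97,
                 "mid": 0.5, "nt": 0.03}
        scores, mapping = self._scores(means)
        classes = classify_barcodes(
            scores, mapping, ["wt1", "wt2", "nt"], ["stop1", "stop2"]
        )
        assert classes.loc["nt", "class"] == "notLoF"
        assert classes.loc["stop1", "class"] == "LoF"
        assert classes.loc["stop2", "class"] == "LoF"
        assert classes.loc["mid", "class"] == "intermediate"

    def test_crossed_references_raise(self):
        scores, mapping = self._scores({"wt1": 0.9, "stop1": 0.1})
        with pytest.raises(ValueError, match="not separable"):
            classify_barcodes(scores, mapping, ["wt1"], ["stop1"])

    def test_bimodal_barcode_has_elevated_coefficient(self):
        rng = np.random.default_rng(1)
        bimodal = np.r_[rng.normal(0.1, 0.02, 40), rng.normal(0.9, 0.02, 40)]
        unimodal = rng.normal(0.5, 0.05, 80)
        assert bimodality_coefficient(bimodal) > 0.555
        assert bimodality_coefficient(bimodal) > bimodality_coefficient(unimodal)


class TestLofGroupDe:
    def _clusters(self, assignments):
        table = pd.DataFrame(
            [(c, 0, m) for c, m in assignments.items()],
            columns=["cell_id", "cluster", "meta"],
        )
        return ClusterResult(table=table, cluster_nt_pct=pd.Series({0: 0.0}))

    def test_seventy_percent_and_three_cells_boundary(self):
        rng = np.random.default_rng(0)
        cells = {}
        cell_grna = {}
        # gA: 7 of 10 cells in LoF (boundary, included)
        for i in range(10):
            cid = f"a{i}"
            cells[cid] = "LoF" if i < 7 else "notLoF"
            cell_grna[cid] = "gA"
        # gB: 2 of 2 in LoF (below 3-cell floor, excluded)
        for i in range(2):
            cells[f"b{i}"] = "LoF"
            cell_grna[f"b{i}"] = "gB"
        for i in range(12):
            cells[f"n{i}"] = "notLoF"
            cell_grna[f"n{i}"] = "NT1"
        expr = gene_matrix(
            rng.poisson(5, size=(len(cells), 8)), cell_ids=list(cells)
        )
        _, lof_grnas = lof_group_de(
            self._clusters(cells), cell_grna, expr, {"NT1"}
        )
        assert lof_grnas == ["gA"]

    def test_empty_lof_group_warns(self):
        rng = np.random.default_rng(0)
        cells = {f"n{i}": "notLoF" for i in range(12)}
        cell_grna = {c: "NT1" for c in cells}
        expr = gene_matrix(rng.poisson(5, size=(12, 4)), cell_ids=list(cells))
        with pytest.warns(RuntimeWarning, match="empty"):
            table, grnas = lof_group_de(
                self._clusters(cells), cell_grna, expr, {"NT1"}
            )
        assert grnas == [] and table.empty


class TestSofSignature:
    @staticmethod
    def _de(rows):
        df = pd.DataFrame(
            rows, columns=["gene", "auc", "pval", "qval", "significant"]
        )
        df["direction"] = np.where(df["auc"] < 0.5, "down", "up")
        return df

    def test_cutoffs_applied_as_specified(self):
        vs_full = self._de(
            [("g1", 0.8, 0.001, 0.005, True),   # up, significant
             ("g2", 0.8, 0.001, 0.005, True),
             ("g3", 0.2, 0.001, 0.005, True),   # down, significant
             ("g4", 0.9, 0.2, 0.4, False)]      # not significant
        )
        vs_benign = self._de(
            [("g1", 0.50, 0.5, 0.9, False),     # 0.50 > 0.45 -> keep
             ("g2", 0.40, 0.5, 0.9, False),     # 0.40 <= 0.45 -> drop
             ("g3", 0.50, 0.5, 0.9, False),     # 0.50 < 0.55 -> keep
             ("g4", 0.60, 0.5, 0.9, False)]
        )
        lists = sof_gene_signature(vs_full, vs_benign)
        assert lists == {"up": ["g1"], "down": ["g3"]}

    def test_empty_input_warns_and_returns_empty(self):
        with pytest.warns(RuntimeWarning):
            lists = sof_gene_signature(self._de([]), self._de([]))
        assert lists == {"up": [], "down": []}
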