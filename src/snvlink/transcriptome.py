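"""Transcriptome QC, AUC differential expression, clustering and
loss-of-function scoring.

The expression phenotype of each clone is summarised two ways:

* a hard label from Louvain clustering merged into two meta-clusters
  (LoF / notLoF), the notLoF side being the one richer in cells carrying
  non-targeting control gRNAs;
* a continuous *diffusion score*: the first non-trivial diffusion-map
  component of the expression embedding, oriented so reference (NT / WT)
  cells score low and min-max scaled to [0, 1].

Differential expression is non-parametric throughout: per-gene two-sample
Wilcoxon rank-sum with mid-rank ties, reported as the AUC
U/(n_A n_B) — the probability that a random cell of group A expresses the
gene more highly than a random cell of group B — with Benjamini-Hochberg
control across genes.  A parametric count model is deliberately avoided:
cells sharing a barcode may be perturbed to different degrees (the
separation-of-function clones are the extreme case).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.sparse.csgraph import connected_components
from scipy.stats import kurtosis, mannwhitneyu, skew
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix


@dataclass
class AnalysisParams:
    """Tunables of the transcriptome stage."""

    n_neighbors: int = 10
    n_pcs: int = 20
    fdr_level: float = 0.1
    lof_group_min_fraction: float = 0.70
    lof_group_min_cells: int = 3
    min_cells_per_barcode_de: int = 10
    sof_auc_up_floor: float = 0.45
    sof_auc_down_ceiling: float = 0.55
    qc_mad_multiplier: float = 3.0
    nt_reference_subsample: int = 500  # cap on reference cells in DE scans
    wt_percentile: float = 95.0        # notLoF anchor on WT barcode means
    stop_percentile: float = 5.0       # LoF anchor on stop-barcode means

    def __post_init__(self) -> None:
        for name in ("fdr_level", "lof_group_min_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("n_neighbors", "n_pcs", "lof_group_min_cells",
                     "min_cells_per_barcode_de"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


def log_normalize(expr: CountMatrix) -> np.ndarray:
    """log1p of counts scaled to the median library size (dense float32)."""
    x = np.asarray(expr.matrix.todense(), dtype=np.float64)
    lib = x.sum(axis=1)
    lib[lib == 0] = 1.0
    x = x * (np.median(lib) / lib)[:, None]
    return np.log1p(x).astype(np.float32)


def qc_filter(
    expr: CountMatrix,
    mito_mask: np.ndarray | None = None,
    mad_multiplier: float = 3.0,
):
    """Remove low-quality cells by MAD-based outlier rules.

    Cells are removed if they are low outliers for the (log) total count,
    low outliers for the (log) number of detected features, or high
    outliers for the mitochondrial count percentage — each rule at
    ``median +/- mad_multiplier * MAD`` in its stated direction.  With an
    empty mitochondrial set the third rule passes vacuously.

    Returns ``(filtered, report)``.
    """
    m = expr.matrix
    totals = np.asarray(m.sum(axis=1)).ravel().astype(float)
    n_features = np.asarray((m > 0).sum(axis=1)).ravel().astype(float)

    def low_outlier(values):
        med = np.median(values)
        mad = np.median(np.abs(values - med))
        return values < med - mad_multiplier * mad

    drop_total = low_outlier(np.log1p(totals))
    drop_feat = low_outlier(np.log1p(n_features))
    if mito_mask is not None and np.any(mito_mask):
        mito_pct = (
            100.0 * np.asarray(m[:, np.asarray(mito_mask, bool)].sum(axis=1)).ravel()
            / np.maximum(totals, 1.0)
        )
        med = np.median(mito_pct)
        mad = np.median(np.abs(mito_pct - med))
        drop_mito = mito_pct > med + mad_multiplier * mad
    else:
        drop_mito = np.zeros(expr.n_cells, dtype=bool)

    drop = drop_total | drop_feat | drop_mito
    if drop.all():
        raise ValueError("QC removed every cell; inspect the input matrix")
    keep = ~drop
    filtered = CountMatrix(
        expr.matrix[keep].tocsr(), expr.cell_ids[keep],
        expr.feature_ids, expr.feature_classes,
    )
    report = {
        "n_input": expr.n_cells,
        "n_kept": int(keep.sum()),
        "removed_low_total": int(drop_total.sum()),
        "removed_low_features": int(drop_feat.sum()),
        "removed_high_mito": int(drop_mito.sum()),
    }
    return filtered, report


def de_auc(
    values_a: np.ndarray,
    values_b: np.ndarray,
    gene_ids,
    fdr_level: float = 0.1,
) -> pd.DataFrame:
    """Per-gene rank-sum AUC differential expression, A versus B.

    ``values_a`` / ``values_b`` are cells x genes expression arrays of the
    two disjoint groups.  AUC = U/(n_A n_B) with mid-rank tie handling;
    p-values are two-sided asymptotic rank-sum, BH-adjusted across genes.
    AUC > 0.5 means upregulation in A.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a.shape[0], b.shape[0]
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = mannwhitneyu(a, b, axis=0, method="asymptotic")
    auc = res.statistic / (n_a * n_b)
    pval = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    _, qval, _, _ = multipletests(pval, method="fdr_bh")
    qval = np.maximum(qval, pval)
    out = pd.DataFrame(
        {
            "gene": list(gene_ids),
            "auc": auc,
            "pval": pval,
            "qval": qval,
        }
    )
    out["direction"] = np.where(out["auc"] < 0.5, "down", "up")
    out.loc[out["auc"] == 0.5, "direction"] = "none"
    out["significant"] = out["qval"] <= fdr_level
    return out


def de_auc_cells(
    expr_values: np.ndarray,
    cell_ids,
    cells_a,
    cells_b,
    gene_ids,
    fdr_level: float = 0.1,
) -> pd.DataFrame:
    """:func:`de_auc` addressed by cell ids over a shared matrix."""
    cells_a, cells_b = list(cells_a), list(cells_b)
    if set(cells_a) & set(cells_b):
        raise ValueError("groups A and B overlap")
    index = {c: i for i, c in enumerate(cell_ids)}
    ia = [index[c] for c in cells_a]
    ib = [index[c] for c in cells_b]
    return de_auc(expr_values[ia], expr_values[ib], gene_ids, fdr_level)


@dataclass
class Embedding:
    """PCA embedding over a selected gene set."""

    coords: np.ndarray
    cell_ids: np.ndarray
    genes: list


def select_features_and_embed(
    expr: CountMatrix,
    cell_grna: dict,
    nt_grnas: set,
    pathway_genes,
    params: AnalysisParams | None = None,
    seed: int = 0,
) -> Embedding:
    """PCA on genes DE for any well-covered gRNA, plus pathway genes.

    For every gRNA with at least ``min_cells_per_barcode_de`` assigned
    cells, genes DE versus the non-targeting cells (BH level
    ``fdr_level``) are collected; the embedding is a PCA over the union of
    those genes and ``pathway_genes``.  The non-targeting reference is
    subsampled (seeded) to ``nt_reference_subsample`` cells for the scan.
    """
    params = params or AnalysisParams()
    values = log_normalize(expr)
    cell_ids = expr.cell_ids
    gene_ids = list(expr.feature_ids)

    nt_cells = [c for c in cell_ids if cell_grna.get(c) in nt_grnas]
    if not nt_cells:
        raise ValueError("no non-targeting cells present")
    rng = np.random.default_rng(seed)
    if len(nt_cells) > params.nt_reference_subsample:
        idx = rng.choice(
            len(nt_cells), size=params.nt_reference_subsample, replace=False
        )
        nt_ref = [nt_cells[i] for i in sorted(idx)]
    else:
        nt_ref = nt_cells

    by_grna: dict[str, list] = {}
    for c in cell_ids:
        g = cell_grna.get(c)
        if g is not None and g not in nt_grnas:
            by_grna.setdefault(g, []).append(c)

    de_genes: set = set()
    for g, cells in sorted(by_grna.items()):
        if len(cells) < params.min_cells_per_barcode_de:
            continue
        res = de_auc_cells(
            values, cell_ids, cells, nt_ref, gene_ids, params.fdr_level
        )
        de_genes |= set(res.loc[res["significant"], "gene"])

    union = sorted(de_genes | set(pathway_genes))
    union = [g for g in union if g in set(gene_ids)]
    if not union:
        raise ValueError("empty union gene set: no DE genes and no pathway genes")
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    cols = [gene_index[g] for g in union]
    sub = values[:, cols]
    n_pcs = min(params.n_pcs, len(union), expr.n_cells - 1)
    pca = PCA(n_components=n_pcs, random_state=seed)
    coords = pca.fit_transform(sub - sub.mean(axis=0, keepdims=True))
    # fix sign convention: largest-|loading| entry of each PC positive
    for k in range(coords.shape[1]):
        j = np.argmax(np.abs(pca.components_[k]))
        if pca.components_[k, j] < 0:
            coords[:, k] *= -1
    return Embedding(coords=coords, cell_ids=cell_ids, genes=union)


@dataclass
class ClusterResult:
    """Fine Louvain clusters merged into two meta-clusters."""

    table: pd.DataFrame        # cell_id, cluster, meta  (meta in LoF/notLoF)
    cluster_nt_pct: pd.Series  # fine cluster -> % NT cells

    def meta_of(self) -> dict:
        return dict(zip(self.table["cell_id"], self.table["meta"]))


def cluster_and_merge(
    embedding: Embedding,
    nt_flags: dict,
    n_neighbors: int = 10,
) -> ClusterResult:
    """Louvain clustering on the kNN graph, merged to two meta-clusters.

    Fine communities come from multilevel modularity optimisation on the
    ``n_neighbors``-NN graph of the embedding; they are merged into
    exactly two meta-clusters by average-linkage hierarchical clustering
    of their centroids, and the meta-cluster with the higher percentage of
    non-targeting cells is labelled ``notLoF``.  Cells are ordered by id
    internally, so the partition is invariant to input order.
    """
    n = len(embedding.cell_ids)
    if n < 2 * n_neighbors:
        raise ValueError(f"need at least {2 * n_neighbors} cells")
    order = np.argsort(embedding.cell_ids.astype(str), kind="stable")
    coords = embedding.coords[order]
    cells = embedding.cell_ids[order]

    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    edges = {
        (min(i, j), max(i, j))
        for i in range(n)
        for j in idx[i, 1:]
    }
    graph = igraph.Graph(n=n, edges=sorted(edges), directed=False)
    part = graph.community_multilevel()
    labels = np.asarray(part.membership)
    if len(set(labels)) < 2:
        raise ValueError(
            "community detection found a single cluster; "
            "increase the clustering resolution or check the embedding"
        )

    k_fine = labels.max() + 1
    centroids = np.vstack([coords[labels == c].mean(axis=0) for c in range(k_fine)])
    if k_fine == 2:
        meta_fine = np.array([0, 1])
    else:
        meta_fine = fcluster(
            linkage(centroids, method="average"), t=2, criterion="maxclust"
        ) - 1
    meta = meta_fine[labels]

    is_nt = np.array([bool(nt_flags.get(c, False)) for c in cells])
    nt_pct_meta = [
        100.0 * is_nt[meta == m].mean() if (meta == m).any() else 0.0
        for m in (0, 1)
    ]
    not_lof_meta = int(np.argmax(nt_pct_meta))
    meta_labels = np.where(meta == not_lof_meta, "notLoF", "LoF")

    cluster_nt_pct = pd.Series(
        {
            c: 100.0 * is_nt[labels == c].mean()
            for c in range(k_fine)
        }
    )
    table = pd.DataFrame(
        {"cell_id": cells, "cluster": labels, "meta": meta_labels}
    )
    return ClusterResult(table=table, cluster_nt_pct=cluster_nt_pct)


@dataclass
class DiffusionResult:
    """Per-cell diffusion scores (first component, oriented, in [0, 1])."""

    scores: pd.Series  # indexed by cell_id


def diffusion_score(
    embedding: Embedding,
    reference_low_cells,
    n_neighbors: int = 10,
    n_components: int = 10,
    bridge_components: bool = False,
) -> DiffusionResult:
    """First diffusion-map component of the embedding.

    A Gaussian kernel with per-cell adaptive bandwidth (distance to the
    ``n_neighbors``-th neighbor) is built on the kNN graph, density
    normalised, and its first non-trivial eigenvector taken as the score
    — the trajectory from the reference (wild-type-like) state towards
    full loss of function.  The sign is oriented so the reference cells
    score low; scores are min-max scaled to [0, 1].
    """
    # exact duplicate cells must share scores: collapse identical
    # coordinates, diffuse on the unique points, broadcast back
    coords, inverse = np.unique(
        np.asarray(embedding.coords, dtype=np.float64).round(12),
        axis=0, return_inverse=True,
    )
    n = coords.shape[0]
    if n < 3:
        raise ValueError("need at least 3 distinct embedding points")
    k = min(n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    dist, idx = nn.kneighbors(coords)
    sigma = np.maximum(dist[:, -1], 1e-12)

    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()
    d2 = (dist[:, 1:] ** 2).ravel()
    vals = np.exp(-d2 / (sigma[rows] * sigma[cols]))
    w = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    w = w.maximum(w.T)

    n_comp, comp_labels = connected_components(w, directed=False)
    if n_comp > 1:
        if not bridge_components:
            raise ValueError(
                f"kernel graph has {n_comp} connected components; "
                "increase the kernel width / neighbor count"
            )
        w = _bridge(w, coords, comp_labels, n_comp)

    q = np.asarray(w.sum(axis=1)).ravel()
    k_mat = sp.diags(1.0 / q) @ w @ sp.diags(1.0 / q)
    d = np.asarray(k_mat.sum(axis=1)).ravel()
    d_inv_sqrt = sp.diags(1.0 / np.sqrt(d))
    a = d_inv_sqrt @ k_mat @ d_inv_sqrt
    a = (a + a.T) / 2
    n_eig = min(n_components + 1, n - 1)
    # fixed Lanczos start vector: eigsh's default draws from the global
    # RNG, which would make scores run-order dependent
    v0 = np.full(n, 1.0 / np.sqrt(n))
    eigvals, eigvecs = sp.linalg.eigsh(a, k=n_eig, which="LA", v0=v0)
    order = np.argsort(eigvals)[::-1]
    phi = d_inv_sqrt @ eigvecs[:, order[1]]

    score = pd.Series(phi[inverse], index=embedding.cell_ids)
    ref = [c for c in reference_low_cells if c in score.index]
    if not ref:
        raise ValueError("no reference cells present in the embedding")
    if score.loc[ref].mean() > score.mean():
        score = -score
    score = (score - score.min()) / (score.max() - score.min())
    return DiffusionResult(scores=score)


def _bridge(w, coords, comp_labels, n_comp):
    """Connect kernel-graph components through their closest cross pairs.

    Each disconnected component is tied to the nearest other component by
    one edge between their mutually closest cells, weighted by a floor
    fraction of the median existing affinity, so the diffusion operator is
    irreducible while between-state transitions stay rare.
    """
    floor = 1e-3 * float(np.median(w.data))
    w = w.tolil()
    reps = [np.where(comp_labels == c)[0] for c in range(n_comp)]
    for c in range(1, n_comp):
        best = None
        for c2 in range(n_comp):
            if c2 == c:
                continue
            a, b = reps[c], reps[c2]
            # closest pair via centroid pre-screen then exact search
            sub_a = a if len(a) <= 500 else a[
                np.argsort(
                    np.linalg.norm(coords[a] - coords[b].mean(axis=0), axis=1)
                )[:500]
            ]
            sub_b = b if len(b) <= 500 else b[
                np.argsort(
                    np.linalg.norm(coords[b] - coords[a].mean(axis=0), axis=1)
                )[:500]
            ]
            d = np.linalg.norm(
                coords[sub_a][:, None, :] - coords[sub_b][None, :, :], axis=2
            )
            i, j = np.unravel_index(np.argmin(d), d.shape)
            if best is None or d[i, j] < best[0]:
                best = (d[i, j], sub_a[i], sub_b[j])
        _, i, j = best
        w[i, j] = max(w[i, j], floor)
        w[j, i] = max(w[j, i], floor)
    return w.tocsr()


def bimodality_coefficient(x: np.ndarray) -> float:
    """Sarle's bimodality coefficient; > ~0.555 suggests bimodality."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 or np.allclose(x, x[0]):
        return np.nan
    g1 = skew(x, bias=False)
    g2 = kurtosis(x, bias=False)
    return (g1 ** 2 + 1) / (g2 + 3 * (n - 1) ** 2 / ((n - 2) * (n - 3)))


def classify_barcodes(
    scores: pd.Series,
    cell_barcode: dict,
    wt_barcodes,
    stop_barcodes,
    params: AnalysisParams | None = None,
) -> pd.DataFrame:
    """Classify barcodes as notLoF / intermediate / LoF by mean score.

    Thresholds are anchored on the reference genotypes: the notLoF bound
    is the ``wt_percentile`` of WT-barcode mean scores and the LoF bound
    the ``stop_percentile`` of stop-codon-barcode mean scores (inclusive).
    Sarle's bimodality coefficient of the per-cell scores is reported per
    barcode; elevated values for intermediate barcodes indicate a
    stochastic (separation-of-function) response.
    """
    params = params or AnalysisParams()
    barcode_of = pd.Series(
        [cell_barcode.get(c) for c in scores.index], index=scores.index
    )
    groups = scores.groupby(barcode_of)
    means = groups.mean()
    wt_means = means.reindex([b for b in wt_barcodes if b in means.index]).dropna()
    stop_means = means.reindex(
        [b for b in stop_barcodes if b in means.index]
    ).dropna()
    if wt_means.empty or stop_means.empty:
        raise ValueError("need at least one WT and one stop/splice barcode")
    low = float(np.percentile(wt_means, params.wt_percentile, method="higher"))
    high = float(np.percentile(stop_means, params.stop_percentile, method="lower"))
    if low > high:
        raise ValueError(
            f"reference barcode scores are not separable (WT bound {low:.3f} "
            f"> stop bound {high:.3f})"
        )
    rows = []
    for barcode, vals in groups:
        mean = float(means[barcode])  # same reduction as the anchors (ulp-exact)
        if mean >= high:
            cls = "LoF"
        elif mean <= low:
            cls = "notLoF"
        else:
            cls = "intermediate"
        rows.append(
            (barcode, len(vals), mean, bimodality_coefficient(vals.to_numpy()), cls)
        )
    return pd.DataFrame(
        rows, columns=["barcode", "n_cells", "mean_score", "bimodality", "class"]
    ).set_index("barcode")


def lof_group_de(
    clusters: ClusterResult,
    cell_grna: dict,
    expr: CountMatrix,
    nt_grnas: set,
    params: AnalysisParams | None = None,
) -> tuple[pd.DataFrame, list]:
    """DE of the LoF gRNA group versus non-targeting cells.

    A gRNA joins the LoF group if at least ``lof_group_min_fraction`` of
    its cells and at least ``lof_group_min_cells`` cells are in the LoF
    meta-cluster.  Returns ``(DE table, LoF-group gRNA list)``; both empty
    (with a warning) if no gRNA qualifies.
    """
    params = params or AnalysisParams()
    meta = clusters.meta_of()
    by_grna: dict[str, list] = {}
    for c, m in meta.items():
        g = cell_grna.get(c)
        if g is not None and g not in nt_grnas:
            by_grna.setdefault(g, []).append((c, m))
    lof_grnas = []
    for g, cells in sorted(by_grna.items()):
        n_lof = sum(1 for _, m in cells if m == "LoF")
        if n_lof >= params.lof_group_min_cells and n_lof >= (
            params.lof_group_min_fraction * len(cells)
        ):
            lof_grnas.append(g)
    if not lof_grnas:
        warnings.warn("LoF group is empty; no DE performed", RuntimeWarning)
        return pd.DataFrame(
            columns=["gene", "auc", "pval", "qval", "direction", "significant"]
        ), []
    lof_cells = [
        c for c in expr.cell_ids
        if cell_grna.get(c) in set(lof_grnas) and c in meta
    ]
    nt_cells = [c for c in expr.cell_ids if cell_grna.get(c) in nt_grnas]
    values = log_normalize(expr)
    res = de_auc_cells(
        values, expr.cell_ids, lof_cells, nt_cells,
        list(expr.feature_ids), params.fdr_level,
    )
    return res, lof_grnas


def barcode_de_correlation(
    expr: CountMatrix,
    cell_barcode: dict,
    reference_cells,
    params: AnalysisParams | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlation of per-barcode DE AUC vectors against a WT reference.

    For every barcode with at least ``min_cells_per_barcode_de`` cells,
    DE versus the reference (WT-genotype plus NT cells, subsampled to
    ``nt_reference_subsample``) yields an AUC vector; Pearson correlations
    are computed over the union of genes significant for at least one
    barcode, and barcodes are ordered by average-linkage hierarchical
    clustering for reporting.

    Returns ``(correlation matrix, AUC matrix)`` (barcodes x barcodes /
    barcodes x genes).
    """
    params = params or AnalysisParams()
    values = log_normalize(expr)
    cell_ids = expr.cell_ids
    gene_ids = list(expr.feature_ids)
    reference_cells = [c for c in reference_cells if c in set(cell_ids)]
    rng = np.random.default_rng(seed)
    if len(reference_cells) > params.nt_reference_subsample:
        idx = rng.choice(
            len(reference_cells), size=params.nt_reference_subsample, replace=False
        )
        reference_cells = [reference_cells[i] for i in sorted(idx)]
    ref_set = set(reference_cells)

    by_barcode: dict[str, list] = {}
    for c in cell_ids:
        b = cell_barcode.get(c)
        if b is not None and c not in ref_set:
            by_barcode.setdefault(b, []).append(c)
    eligible = {
        b: cells for b, cells in by_barcode.items()
        if len(cells) >= params.min_cells_per_barcode_de
    }
    if not eligible:
        raise ValueError(
            f"no barcode reaches {params.min_cells_per_barcode_de} cells"
        )
    auc_rows, sig_union = {}, set()
    for b, cells in sorted(eligible.items()):
        res = de_auc_cells(
            values, cell_ids, cells, reference_cells, gene_ids, params.fdr_level
        )
        auc_rows[b] = res["auc"].to_numpy()
        sig_union |= set(res.loc[res["significant"], "gene"])
    auc_matrix = pd.DataFrame(auc_rows, index=gene_ids).T
    genes = sorted(sig_union) if sig_union else gene_ids
    sub = auc_matrix[genes]
    corr = sub.T.corr(method="pearson")
    if len(corr) > 2:
        order = leaves_list(linkage(sub.to_numpy(), method="average"))
        corr = corr.iloc[order, order]
    return corr, auc_matrix


def sof_gene_signature(
    de_sof_vs_full: pd.DataFrame,
    de_sof_vs_benign: pd.DataFrame,
    params: AnalysisParams | None = None,
) -> dict:
    """Genes separating SoF clones from the LoF-to-benign trajectory.

    Up list: significantly up for SoF versus full-impact missense AND not
    down versus benign (AUC > ``sof_auc_up_floor``).  Down list:
    significantly down versus full-impact AND not up versus benign
    (AUC < ``sof_auc_down_ceiling``).
    """
    params = params or AnalysisParams()
    if de_sof_vs_full.empty or de_sof_vs_benign.empty:
        warnings.warn("a SoF comparison stratum is empty", RuntimeWarning)
        return {"up": [], "down": []}
    benign_auc = de_sof_vs_benign.set_index("gene")["auc"]
    full = de_sof_vs_full.set_index("gene")
    up = full[
        full["significant"] & (full["auc"] > 0.5)
        & (benign_auc.reindex(full.index) > params.sof_auc_up_floor)
    ]
    down = full[
        full["significant"] & (full["auc"] < 0.5)
        & (benign_auc.reindex(full.index) < params.sof_auc_down_ceiling)
    ]
    return {"up": sorted(up.index), "down": sorted(down.index)}
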