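"""Linking consensus genotypes to transcriptomes and evaluating the calls.

The two modalities never share cells; they share barcodes.  An RNA cell
whose gRNA+iBAR combination (or mapped puroR) matches a barcode group with
a callable consensus genotype inherits that genotype.  Genotype-call
quality is then audited against the transcriptome phenotype: barcodes
called stop/splice should carry a loss-of-function expression state and
barcodes called WT should not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .containers import CountMatrix, EvalReport
from .transcriptome import log_normalize


def link_rna_to_genotype(
    rna_co_assignments: pd.DataFrame,
    consensus_by_group: dict,
    puror_mapping: dict,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach consensus genotypes to RNA cells through their barcodes.

    ``rna_co_assignments`` is the per-cell frame from
    :func:`snvlink.assign.co_assign` on the RNA modality;
    ``consensus_by_group`` maps the group key ``"gRNA|iBAR"`` to a
    :class:`~snvlink.containers.ConsensusGenotype`.  Returns
    ``(linked, unlinked)`` where ``linked`` has one row per linked cell
    (group id, status, consequence) and ``unlinked`` carries a reason.
    """
    linked, unlinked = [], []
    for row in rna_co_assignments.itertuples(index=False):
        if row.unique_grna_ibar:
            key = f"{row.grna}|{row.ibar}"
        elif row.unique_puror and row.puror in puror_mapping:
            g, i = puror_mapping[row.puror]
            key = f"{g}|{i}"
        else:
            unlinked.append((row.cell_id, "no_barcode"))
            continue
        geno = consensus_by_group.get(key)
        if geno is None:
            unlinked.append((row.cell_id, "barcode_not_genotyped"))
        elif geno.status == "uncallable":
            unlinked.append((row.cell_id, "uncallable_genotype"))
        else:
            linked.append(
                (row.cell_id, key, geno.status, geno.consequence)
            )
    linked = pd.DataFrame(
        linked, columns=["cell_id", "group_id", "status", "consequence"]
    )
    unlinked = pd.DataFrame(unlinked, columns=["cell_id", "reason"])
    return linked, unlinked


def build_joint_embedding(
    reference_expr: CountMatrix,
    query_expr: CountMatrix,
    genes,
    n_pcs: int = 20,
    seed: int = 0,
):
    """Per-gene centred joint PCA of two datasets on a shared gene space.

    Each dataset is log-normalised and centred per gene before stacking —
    a deliberately simple stand-in for mutual-nearest-neighbour batch
    correction; any externally corrected joint embedding can be supplied
    to :func:`transfer_labels` instead.
    """
    genes = list(genes)
    out = []
    for expr in (reference_expr, query_expr):
        idx = {g: i for i, g in enumerate(expr.feature_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise ValueError(f"genes absent from a dataset: {missing[:5]}")
        v = log_normalize(expr)[:, [idx[g] for g in genes]]
        out.append(v - v.mean(axis=0, keepdims=True))
    stacked = np.vstack(out)
    n_pcs = min(n_pcs, stacked.shape[1], stacked.shape[0] - 1)
    pca = PCA(n_components=n_pcs, random_state=seed)
    coords = pca.fit_transform(stacked)
    n_ref = reference_expr.n_cells
    return coords[:n_ref], coords[n_ref:]


def transfer_labels(
    reference_coords: np.ndarray,
    reference_cell_ids,
    reference_labels: dict,
    query_coords: np.ndarray,
    query_cell_ids,
    reference_extra_coords: np.ndarray | None = None,
    k: int = 10,
) -> pd.DataFrame:
    """k-NN label transfer from a reference embedding to query cells.

    Each query cell takes the coordinates (``reference_extra_coords``,
    e.g. a 2-D layout) of its single nearest reference neighbor and the
    modal label among its ``k`` nearest reference neighbors; a modal tie
    is broken toward the label whose member is nearest.  Neighbor-distance
    ties are broken by reference cell id for determinism.
    """
    reference_cell_ids = np.asarray(reference_cell_ids, dtype=object)
    n_ref = len(reference_cell_ids)
    if k > n_ref:
        raise ValueError(f"k={k} exceeds reference size {n_ref}")
    order = np.lexsort((reference_cell_ids.astype(str),))
    ref = np.asarray(reference_coords, dtype=float)[order]
    ref_ids = reference_cell_ids[order]
    extra = (
        np.asarray(reference_extra_coords, dtype=float)[order]
        if reference_extra_coords is not None
        else ref
    )
    nn = NearestNeighbors(n_neighbors=k).fit(ref)
    dist, idx = nn.kneighbors(np.asarray(query_coords, dtype=float))

    rows = []
    for qi, cell in enumerate(query_cell_ids):
        neighbor_ids = ref_ids[idx[qi]]
        labels = [reference_labels[r] for r in neighbor_ids]
        counts = pd.Series(labels).value_counts()
        top = counts[counts == counts.max()].index
        if len(top) == 1:
            label = top[0]
        else:  # tie: the label whose nearest member is closest wins
            best = {}
            for rank, lab in enumerate(labels):
                if lab in set(top) and lab not in best:
                    best[lab] = rank
            label = min(best, key=lambda lab: (best[lab], str(lab)))
        nearest = extra[idx[qi, 0]]
        rows.append(
            (cell, label, float(nearest[0]),
             float(nearest[1]) if len(nearest) > 1 else 0.0)
        )
    return pd.DataFrame(rows, columns=["cell_id", "label", "coord_1", "coord_2"])


def filter_lone_barcode_cells(
    linked: pd.DataFrame, barcode_col: str = "group_id", cluster_col: str = "label"
) -> pd.DataFrame:
    """Drop cells that are the only member of their barcode in a cluster.

    Denoises barcode-assignment errors: one stray cell of a barcode inside
    a cluster dominated by other barcodes is more likely a misassigned
    barcode than a real phenotype.
    """
    sizes = linked.groupby([barcode_col, cluster_col])[barcode_col].transform("size")
    return linked[sizes > 1].reset_index(drop=True)


def evaluate_classification(
    barcode_classes: pd.DataFrame,
    positive_consequences=("stop_gained", "splice"),
) -> EvalReport:
    """Confusion of genotype calls against transcriptome phenotype.

    ``barcode_classes`` needs a ``consequence`` column (genotype call:
    ``WT`` or a consequence class) and a ``phenotype`` column (``LoF`` /
    ``notLoF`` from the diffusion score).  Barcodes called stop/splice are
    the positive class; barcodes called WT the negative class; everything
    else is ignored.
    """
    cons = barcode_classes["consequence"]
    pheno = barcode_classes["phenotype"]
    pos = cons.isin(positive_consequences)
    neg = cons == "WT"
    lof = pheno == "LoF"
    return EvalReport(
        tp=int((pos & lof).sum()),
        fp=int((pos & ~lof).sum()),
        fn=int((neg & lof).sum()),
        tn=int((neg & ~lof).sum()),
    )


@dataclass
class LinkageSummary:
    """Overlap of the two barcode systems on the DNA modality."""

    n_unique_puror: int
    n_unique_grna_ibar: int
    n_both: int

    def __post_init__(self) -> None:
        if self.n_both > min(self.n_unique_puror, self.n_unique_grna_ibar):
            raise ValueError("n_both exceeds a marginal count")

    @property
    def fraction_puror_with_grna_ibar(self) -> float:
        return self.n_both / self.n_unique_puror

    @property
    def fraction_grna_ibar_with_puror(self) -> float:
        return self.n_both / self.n_unique_grna_ibar

    @property
    def pct_puror_with_grna_ibar(self) -> int:
        return round(100 * self.fraction_puror_with_grna_ibar)

    @property
    def pct_grna_ibar_with_puror(self) -> int:
        return round(100 * self.fraction_grna_ibar_with_puror)


def summarize_linkage(co_assignments: pd.DataFrame) -> LinkageSummary:
    """Counts and overlap fractions of puroR versus gRNA+iBAR assignment."""
    if len(co_assignments) == 0:
        raise ValueError("no cells in co-assignment table")
    return LinkageSummary(
        n_unique_puror=int(co_assignments["unique_puror"].sum()),
        n_unique_grna_ibar=int(co_assignments["unique_grna_ibar"].sum()),
        n_both=int(co_assignments["both"].sum()),
    )


def concordance_summary(records) -> dict:
    """Summarise gRNA-prediction concordance records.

    ``records`` come from :func:`snvlink.consensus.compare_to_prediction`.
    Returns nucleotide- and protein-level concordant fractions and the
    breakdown of discordance reasons among protein-discordant records.
    """
    records = list(records)
    if not records:
        raise ValueError("no comparison records")
    n = len(records)
    nuc = sum(r["nucleotide_match"] for r in records)
    prot = sum(r["protein_match"] for r in records)
    reasons = pd.Series(
        [r["discordance_reason"] for r in records if not r["protein_match"]]
    )
    breakdown = (
        (reasons.value_counts() / len(reasons)).to_dict() if len(reasons) else {}
    )
    return {
        "n": n,
        "fraction_nucleotide_concordant": nuc / n,
        "fraction_protein_concordant": prot / n,
        "pct_nucleotide_concordant": round(100 * nuc / n),
        "pct_protein_concordant": round(100 * prot / n),
        "discordance_breakdown": breakdown,
    }
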