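"""Per-cell barcode assignment from UMI counts and fitted thresholds.

A feature (gRNA, iBAR or puroR barcode) is called in a cell iff its UMI
count exceeds the upper threshold while no other feature of the same class
exceeds the lower threshold.  Cells with two features above the lower
threshold are left unassigned as ambiguous — this is also what removes most
doublets, which carry two gRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .containers import CountMatrix
from .mixture import ThresholdPair

REASONS = ("assigned", "no_signal", "ambiguous")


@dataclass
class AssignmentTable:
    """Per-cell single-class assignments.

    ``table`` has columns ``cell_id``, ``feature_id`` (empty string when
    unassigned) and ``reason`` in ``assigned | no_signal | ambiguous``.
    """

    feature_class: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.table.columns) != ["cell_id", "feature_id", "reason"]:
            raise ValueError("assignment table columns must be cell_id, feature_id, reason")
        bad = set(self.table["reason"]) - set(REASONS)
        if bad:
            raise ValueError(f"unknown reasons: {sorted(bad)}")

    @property
    def assigned(self) -> pd.DataFrame:
        return self.table[self.table["reason"] == "assigned"]

    def mapping(self) -> dict:
        """cell_id -> feature_id for assigned cells."""
        a = self.assigned
        return dict(zip(a["cell_id"], a["feature_id"]))


def assign_features(
    counts: CountMatrix, thresholds: ThresholdPair, feature_class: str | None = None
) -> AssignmentTable:
    """Assign at most one feature per cell under the dual-threshold rule.

    A cell is assigned feature *f* iff ``count(f) > t_hi`` and every other
    feature's count is ``<= t_lo``; otherwise it is unassigned with reason
    ``no_signal`` (nothing above ``t_hi``) or ``ambiguous`` (a second
    feature above ``t_lo``, or two features above ``t_hi``).
    """
    if feature_class is None:
        classes = set(counts.feature_classes)
        if len(classes) != 1:
            raise ValueError("matrix spans several classes; pass feature_class")
        feature_class = classes.pop()
    else:
        counts = counts.subset_class(feature_class)

    m = counts.matrix.tocsr()
    t_lo, t_hi = thresholds.t_lo, thresholds.t_hi
    rows = []
    for i in range(counts.n_cells):
        start, end = m.indptr[i], m.indptr[i + 1]
        cols = m.indices[start:end]
        vals = m.data[start:end]
        above_hi = cols[vals > t_hi]
        above_lo = cols[vals > t_lo]
        if above_hi.size == 1 and above_lo.size <= 1:
            rows.append((counts.cell_ids[i], counts.feature_ids[above_hi[0]], "assigned"))
        elif above_lo.size >= 2 or above_hi.size >= 2:
            rows.append((counts.cell_ids[i], "", "ambiguous"))
        else:
            rows.append((counts.cell_ids[i], "", "no_signal"))
    table = pd.DataFrame(rows, columns=["cell_id", "feature_id", "reason"])
    return AssignmentTable(feature_class=feature_class, table=table)


def co_assign(
    grna: AssignmentTable, ibar: AssignmentTable, puror: AssignmentTable
) -> pd.DataFrame:
    """Combine per-class calls into per-cell flags.

    Returns a frame with one row per cell: the class-level feature ids
    (empty when unassigned) and boolean flags ``unique_grna_ibar``
    (both gRNA and iBAR assigned), ``unique_puror`` and ``both``.
    """
    cells = list(grna.table["cell_id"])
    for other in (ibar, puror):
        if set(other.table["cell_id"]) != set(cells):
            raise ValueError("assignment tables cover different cell sets")

    g = grna.table.set_index("cell_id")
    i = ibar.table.set_index("cell_id").loc[cells]
    p = puror.table.set_index("cell_id").loc[cells]
    out = pd.DataFrame(
        {
            "cell_id": cells,
            "grna": g.loc[cells, "feature_id"].to_numpy(),
            "ibar": i["feature_id"].to_numpy(),
            "puror": p["feature_id"].to_numpy(),
        }
    )
    out["unique_grna_ibar"] = (out["grna"] != "") & (out["ibar"] != "")
    out["unique_puror"] = out["puror"] != ""
    out["both"] = out["unique_grna_ibar"] & out["unique_puror"]
    return out
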