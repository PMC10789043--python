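"""Core in-memory containers shared across the pipeline.

Conventions used throughout the package:

* genomic coordinates are 1-based inclusive (VCF convention);
* UMI count matrices are cells x features, stored sparse (CSR), with a
  feature-class label (``gene`` | ``gRNA`` | ``iBAR`` | ``puroR``) per column;
* allele dosage is the number of edited alleles at a site, ``0..ploidy``
  (default ploidy 3 for the hypotriploid cancer line the assay was
  developed in).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

FEATURE_CLASSES = ("gene", "gRNA", "iBAR", "puroR")

#: columns of a per-cell variant table
VARIANT_COLUMNS = ["cell_id", "chrom", "pos", "ref", "alt", "dosage"]


@dataclass
class CountMatrix:
    """Sparse cells x features UMI count matrix with feature-class labels."""

    matrix: sp.csr_matrix
    cell_ids: np.ndarray
    feature_ids: np.ndarray
    feature_classes: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.feature_classes = np.asarray(self.feature_classes, dtype=object)
        n, m = self.matrix.shape
        if len(self.cell_ids) != n:
            raise ValueError(
                f"cell_ids length {len(self.cell_ids)} != matrix rows {n}"
            )
        if len(self.feature_ids) != m or len(self.feature_classes) != m:
            raise ValueError(
                f"feature annotation length != matrix columns {m}"
            )
        unknown = set(self.feature_classes) - set(FEATURE_CLASSES)
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def subset_class(self, feature_class: str) -> "CountMatrix":
        """Return the sub-matrix of one feature class (same cells)."""
        mask = self.feature_classes == feature_class
        return CountMatrix(
            self.matrix[:, mask].tocsr(),
            self.cell_ids,
            self.feature_ids[mask],
            self.feature_classes[mask],
        )

    def subset_cells(self, cell_ids) -> "CountMatrix":
        index = {c: i for i, c in enumerate(self.cell_ids)}
        rows = np.array([index[c] for c in cell_ids], dtype=int)
        return CountMatrix(
            self.matrix[rows].tocsr(),
            np.asarray(list(cell_ids), dtype=object),
            self.feature_ids,
            self.feature_classes,
        )

    def to_anndata(self):
        """Convert to :class:`anndata.AnnData` (optional dependency)."""
        import anndata as ad

        return ad.AnnData(
            X=self.matrix.copy(),
            obs=pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id")),
            var=pd.DataFrame(
                {"feature_class": self.feature_classes},
                index=pd.Index(self.feature_ids, name="feature_id"),
            ),
        )


def validate_variant_table(table: pd.DataFrame, ploidy: int = 3) -> pd.DataFrame:
    """Validate a per-cell variant table (``VARIANT_COLUMNS`` schema).

    Rows must have 1-based positions, ACGT ref/alt with ref != alt and
    dosage in ``0..ploidy``.  Returns a copy with canonical dtypes.
    """
    missing = [c for c in VARIANT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    out = table[VARIANT_COLUMNS].copy()
    out["pos"] = out["pos"].astype(np.int64)
    out["dosage"] = out["dosage"].astype(np.int64)
    bases = {"A", "C", "G", "T"}
    ok = (
        (out["pos"] >= 1)
        & out["ref"].isin(bases)
        & out["alt"].isin(bases)
        & (out["ref"] != out["alt"])
        & (out["dosage"] >= 0)
        & (out["dosage"] <= ploidy)
    )
    if not ok.all():
        bad = out.index[~ok].tolist()
        raise ValueError(f"invalid variant rows at index {bad[:10]}")
    return out.reset_index(drop=True)


@dataclass
class BarcodeGroup:
    """A clone: all cells descending from one transduced parent cell."""

    group_id: str
    cell_ids: list
    grna_ibar: tuple | None = None  # (gRNA id, iBAR id)
    puror: str | None = None

    def __post_init__(self) -> None:
        if self.grna_ibar is None and self.puror is None:
            raise ValueError(f"group {self.group_id}: no barcode key present")
        if len(self.cell_ids) < 1:
            raise ValueError(f"group {self.group_id}: empty group")

    @property
    def size(self) -> int:
        return len(self.cell_ids)


@dataclass
class ConsensusGenotype:
    """Per-barcode-group genotype call.

    ``status`` is one of ``WT`` / ``edited`` / ``uncallable``.  ``variants``
    is a list of ``(chrom, pos, ref, alt, dosage)`` tuples (dosage 1..ploidy)
    and is empty unless ``status == "edited"``.
    """

    group_id: str
    status: str
    variants: list = field(default_factory=list)
    zygosity: str | None = None  # homozygous | het1 | het2 | mixed
    consequence: str | None = None
    reason: str | None = None
    n_cells: int = 0

    def __post_init__(self) -> None:
        if self.status not in ("WT", "edited", "uncallable"):
            raise ValueError(f"bad status {self.status!r}")
        if self.status == "WT" and self.variants:
            raise ValueError("WT genotype must carry no variants")


@dataclass
class EvalReport:
    """Confusion counts of genotype calls against phenotype classes."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def precision(self) -> float:
        if self.tp + self.fp == 0:
            raise ZeroDivisionError("precision undefined: no positive calls")
        return self.tp / (self.tp + self.fp)

    @property
    def recall(self) -> float:
        if self.tp + self.fn == 0:
            raise ZeroDivisionError("recall undefined: no positive truths")
        return self.tp / (self.tp + self.fn)

    @property
    def precision_pct(self) -> int:
        return round(100 * self.precision)

    @property
    def recall_pct(self) -> int:
        return round(100 * self.recall)
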