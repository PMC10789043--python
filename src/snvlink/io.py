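"""Readers and writers for the pipeline's on-disk formats.

Canonical formats: MatrixMarket MTX triplet directories for count
matrices (``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``),
tab-separated tables with a header row for everything tabular, and
VCF 4.2 for consensus genotypes (one sample column per barcode group,
dosage in a ``DS`` FORMAT field).  Genomic coordinates are 1-based
inclusive everywhere.  Every writer emits a comment header with the tool
version and the resolved seed, and writes rows in a stable order.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from . import __version__
from .containers import CountMatrix, VARIANT_COLUMNS, validate_variant_table


def _header_comment(seed) -> str:
    return f"snvlink v{__version__} seed={seed}"


def write_count_matrix(counts: CountMatrix, outdir, seed=0) -> None:
    """Write an MTX triplet directory (matrix + features + barcodes)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        str(outdir / "matrix.mtx"),
        counts.matrix.tocoo(),
        comment=_header_comment(seed),
        field="integer",
    )
    with open(outdir / "features.tsv", "w") as fh:
        fh.write(f"# {_header_comment(seed)}\n")
        fh.write("feature_id\tfeature_class\n")
        for fid, fcls in zip(counts.feature_ids, counts.feature_classes):
            fh.write(f"{fid}\t{fcls}\n")
    with open(outdir / "barcodes.tsv", "w") as fh:
        fh.write(f"# {_header_comment(seed)}\n")
        fh.write("cell_id\n")
        for cid in counts.cell_ids:
            fh.write(f"{cid}\n")


def read_count_matrix(path) -> CountMatrix:
    """Read a count matrix from an MTX triplet directory or a dense TSV.

    The MTX directory must contain ``matrix.mtx``, ``features.tsv``
    (columns ``feature_id``, ``feature_class``) and ``barcodes.tsv``
    (column ``cell_id``); a dense TSV has cells as rows, features as
    columns, and feature classes default to ``gene``.
    """
    path = Path(path)
    if path.is_dir():
        mtx_path = path / "matrix.mtx"
        with open(mtx_path) as fh:
            first = fh.readline()
        if not first.startswith("%%MatrixMarket"):
            raise ValueError(
                f"{mtx_path}, line 1: not a MatrixMarket header: {first.strip()!r}"
            )
        try:
            matrix = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
        except ValueError as err:
            raise ValueError(f"{mtx_path}: malformed MTX body: {err}") from err
        features = pd.read_csv(path / "features.tsv", sep="\t", comment="#")
        cells = pd.read_csv(path / "barcodes.tsv", sep="\t", comment="#")
        if matrix.shape != (len(cells), len(features)):
            raise ValueError(
                f"dimension mismatch: {mtx_path} is {matrix.shape} but "
                f"barcodes.tsv has {len(cells)} cells and features.tsv "
                f"{len(features)} features"
            )
        return CountMatrix(
            matrix,
            cells["cell_id"].to_numpy(),
            features["feature_id"].to_numpy(),
            features["feature_class"].to_numpy(),
        )
    dense = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return CountMatrix(
        sp.csr_matrix(dense.to_numpy()),
        dense.index.to_numpy(),
        dense.columns.to_numpy(),
        np.array(["gene"] * dense.shape[1], dtype=object),
    )


def write_variant_table(table: pd.DataFrame, path, seed=0) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_header_comment(seed)}\n")
        table.to_csv(fh, sep="\t", index=False)


def read_variant_table(path, ploidy: int = 3, max_reject_fraction: float = 0.01
                       ) -> pd.DataFrame:
    """Read and validate a per-cell variant TSV.

    Invalid rows (position < 1, non-ACGT or identical ref/alt, dosage
    outside ``0..ploidy``) are rejected with their row numbers; more than
    ``max_reject_fraction`` rejected rows is a hard error.
    """
    raw = pd.read_csv(
        path, sep="\t", comment="#",
        dtype={"cell_id": str, "chrom": str, "ref": str, "alt": str},
    )
    missing = [c for c in VARIANT_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bases = {"A", "C", "G", "T"}
    pos = pd.to_numeric(raw["pos"], errors="coerce")
    dosage = pd.to_numeric(raw["dosage"], errors="coerce")
    ok = (
        pos.notna() & (pos >= 1)
        & raw["ref"].isin(bases) & raw["alt"].isin(bases)
        & (raw["ref"] != raw["alt"])
        & dosage.notna() & (dosage >= 0) & (dosage <= ploidy)
    )
    n_bad = int((~ok).sum())
    if n_bad:
        bad_rows = raw.index[~ok].tolist()
        if n_bad > max_reject_fraction * max(len(raw), 1):
            raise ValueError(
                f"{path}: {n_bad} invalid rows (e.g. rows {bad_rows[:5]}); "
                "above the rejection tolerance"
            )
        import warnings

        warnings.warn(
            f"{path}: rejected {n_bad} invalid rows: {bad_rows[:10]}",
            RuntimeWarning,
        )
    clean = raw[ok].copy()
    clean["pos"] = pos[ok].astype(np.int64)
    clean["dosage"] = dosage[ok].astype(np.int64)
    return validate_variant_table(clean, ploidy=ploidy)


def write_consensus_table(genotypes, path, seed=0) -> None:
    """Write consensus genotypes as a TSV (one row per group)."""
    rows = []
    for g in sorted(genotypes, key=lambda g: g.group_id):
        variant_str = ";".join(
            f"{c}:{p}:{r}>{a}:{d}" for c, p, r, a, d in g.variants
        )
        rows.append(
            (g.group_id, g.n_cells, g.status, variant_str,
             g.zygosity or "", g.consequence or "", g.reason or "")
        )
    table = pd.DataFrame(
        rows,
        columns=["group_id", "n_cells", "status", "variants", "zygosity",
                 "consequence", "reason"],
    )
    with open(path, "w") as fh:
        fh.write(f"# {_header_comment(seed)}\n")
        table.to_csv(fh, sep="\t", index=False)


def write_consensus_vcf(genotypes, path, ploidy: int = 3, seed=0,
                        contig_lengths: dict | None = None) -> None:
    """Write callable consensus genotypes as a VCF 4.2 file.

    One sample column per barcode group; the edited-allele dosage is in
    the ``DS`` FORMAT field and the genotype string encodes ``ploidy``
    alleles.  Positions are sorted on write.
    """
    callable_groups = [g for g in genotypes if g.status in ("WT", "edited")]
    callable_groups.sort(key=lambda g: g.group_id)
    sites: dict[tuple, dict] = {}
    for g in callable_groups:
        for chrom, pos, ref, alt, dosage in g.variants:
            sites.setdefault((chrom, pos, ref, alt), {})[g.group_id] = dosage
    if contig_lengths is None:
        contig_lengths = {}
        for chrom, pos, *_ in sites:
            contig_lengths[chrom] = max(contig_lengths.get(chrom, 0), pos + 1000)

    buf = _io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write(f"##source=snvlink v{__version__} seed={seed}\n")
    buf.write(f"##ploidy={ploidy}\n")
    for chrom in sorted(contig_lengths):
        buf.write(f"##contig=<ID={chrom},length={contig_lengths[chrom]}>\n")
    buf.write(
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    )
    buf.write(
        '##FORMAT=<ID=DS,Number=1,Type=Integer,'
        f'Description="Edited allele dosage (0-{ploidy})">\n'
    )
    sample_ids = [g.group_id for g in callable_groups]
    buf.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(s.replace("|", "_") for s in sample_ids) + "\n"
    )
    for (chrom, pos, ref, alt) in sorted(sites):
        dosages = sites[(chrom, pos, ref, alt)]
        cols = []
        for s in sample_ids:
            d = dosages.get(s, 0)
            gt = "/".join(["1"] * d + ["0"] * (ploidy - d))
            cols.append(f"{gt}:{d}")
        buf.write(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:DS\t"
            + "\t".join(cols) + "\n"
        )
    Path(path).write_text(buf.getvalue())


def write_truth(truth, outdir, seed=0) -> None:
    """Write the ground-truth tables of a simulated screen."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, frame in (
        ("truth_barcodes.tsv", truth.barcodes),
        ("truth_variants.tsv", truth.variants),
        ("truth_cells_dna.tsv", truth.cells_dna),
        ("truth_cells_rna.tsv", truth.cells_rna),
        ("grna_library.tsv", truth.grna_library),
    ):
        with open(outdir / name, "w") as fh:
            fh.write(f"# {_header_comment(seed)}\n")
            frame.to_csv(fh, sep="\t", index=False)
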