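"""End-to-end orchestration: simulate -> call barcodes -> genotype ->
analyse transcriptomes -> link -> evaluate.

`run_pipeline` drives the full synthetic workflow and returns a nested
report of per-stage counts and evaluation statistics mirroring the
reporting style of the assay (cells assigned, groups callable,
precision/recall of stop+splice versus WT calls, concordance with
gRNA-based predictions).  Each stage is also available as a standalone
function for real-data workflows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assign import AssignmentTable, assign_features, co_assign
from .consensus import (
    ConsensusParams,
    GRNARecord,
    assign_consequence,
    call_consensus,
    compare_to_prediction,
    filter_edit_types,
    form_barcode_groups,
    map_puror_to_grna_ibar,
    predict_genotype_from_grna,
    remove_recurrent_artifacts,
    variant_group_incidence,
)
from .containers import CountMatrix
from .linkage import (
    concordance_summary,
    evaluate_classification,
    link_rna_to_genotype,
    summarize_linkage,
)
from .mixture import MixtureFit, ThresholdPair, assignment_thresholds, fit_count_mixture
from .simulate import SimConfig, generate_screen
from .transcriptome import (
    AnalysisParams,
    classify_barcodes,
    cluster_and_merge,
    diffusion_score,
    lof_group_de,
    qc_filter,
    select_features_and_embed,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved configuration of a full synthetic run."""

    sim: SimConfig = field(default_factory=SimConfig)
    consensus: ConsensusParams = field(default_factory=ConsensusParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    seed: int = 0
    min_count: int = 2
    p_lo: float = 0.9
    p_hi: float = 0.1

    def __post_init__(self) -> None:
        self.sim.seed = self.seed


def call_barcode_class(
    counts: CountMatrix,
    feature_class: str,
    min_count: int = 2,
    p_lo: float = 0.9,
    p_hi: float = 0.1,
    seed: int = 0,
    fit: MixtureFit | None = None,
) -> tuple[AssignmentTable, MixtureFit, ThresholdPair]:
    """Fit the count mixture for one class and assign features to cells.

    A precomputed ``fit`` (e.g. from generating parameters in simulation
    studies) bypasses the EM step.
    """
    sub = counts.subset_class(feature_class)
    pooled = sub.matrix.data
    if fit is None:
        fit = fit_count_mixture(pooled, min_count=min_count, seed=seed)
    thresholds = assignment_thresholds(fit, p_lo=p_lo, p_hi=p_hi)
    table = assign_features(sub, thresholds)
    return table, fit, thresholds


def call_all_barcodes(
    counts: CountMatrix,
    min_count: int = 2,
    p_lo: float = 0.9,
    p_hi: float = 0.1,
    seed: int = 0,
    fits: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Assign gRNA, iBAR and puroR barcodes and combine per cell."""
    tables, details = {}, {}
    for cls in ("gRNA", "iBAR", "puroR"):
        table, fit, thr = call_barcode_class(
            counts, cls, min_count=min_count, p_lo=p_lo, p_hi=p_hi, seed=seed,
            fit=None if fits is None else fits.get(cls),
        )
        tables[cls] = table
        details[cls] = {"fit": fit, "thresholds": thr, "table": table}
    combined = co_assign(tables["gRNA"], tables["iBAR"], tables["puroR"])
    return combined, details


def genotype_barcode_groups(
    co_assignments: pd.DataFrame,
    variant_table: pd.DataFrame,
    params: ConsensusParams,
    annotation: dict,
):
    """Form barcode groups and call consensus genotypes.

    Returns ``(consensus dict by group id, groups, puror_mapping,
    excluded cells)``.  The variant table is edit-type filtered and
    recurrent artifacts are removed before calling.
    """
    mapping = map_puror_to_grna_ibar(co_assignments)
    groups, excluded = form_barcode_groups(co_assignments, mapping)
    table = filter_edit_types(variant_table, params)
    incidence = variant_group_incidence(table, groups)
    retained = remove_recurrent_artifacts(
        incidence, n_groups=len(groups),
        recurrence_fraction=params.recurrence_fraction,
    )
    keys = list(zip(table["chrom"], table["pos"], table["ref"], table["alt"]))
    keep = np.array([k in retained for k in keys], dtype=bool)
    table = table[keep]
    consensus = {}
    for group in groups:
        geno = call_consensus(group, table, params)
        geno = assign_consequence(geno, annotation, params)
        consensus[group.group_id] = geno
    return consensus, groups, mapping, excluded


def run_pipeline(
    config: PipelineConfig,
    include_expression: bool = True,
    fits: dict | None = None,
) -> dict:
    """Run the full synthetic screen workflow and collect a report.

    ``fits`` optionally maps feature class to a precomputed
    :class:`~snvlink.mixture.MixtureFit` (e.g. the generating parameters
    in simulation studies), bypassing the per-class EM.
    """
    report: dict = {"seed": config.seed}
    logger.info("simulating screen (%d barcodes)", config.sim.n_barcodes)
    truth, cell_variants, rna_expr, dna_bc, rna_bc = generate_screen(config.sim)
    report["simulated"] = {
        "n_barcodes": config.sim.n_barcodes,
        "n_dna_cells": len(truth.cells_dna),
        "n_rna_cells": len(truth.cells_rna),
    }

    # --- DNA modality: barcode calling and genotyping
    logger.info("calling DNA barcodes")
    dna_co, dna_details = call_all_barcodes(
        dna_bc, min_count=config.min_count, p_lo=config.p_lo, p_hi=config.p_hi,
        seed=config.seed, fits=fits,
    )
    link_summary = summarize_linkage(dna_co)
    report["dna_assignment"] = {
        "n_unique_puror": link_summary.n_unique_puror,
        "n_unique_grna_ibar": link_summary.n_unique_grna_ibar,
        "n_both": link_summary.n_both,
        "pct_puror_with_grna_ibar": link_summary.pct_puror_with_grna_ibar,
        "pct_grna_ibar_with_puror": link_summary.pct_grna_ibar_with_puror,
    }

    params = config.consensus
    if truth.gene_model is not None:  # synthetic promoter interval
        params = ConsensusParams(
            **{
                **params.__dict__,
                "promoter_interval": (
                    truth.gene_model.chrom, *truth.gene_model.promoter
                ),
                "ploidy": config.sim.ploidy,
            }
        )
    logger.info("calling consensus genotypes")
    consensus, groups, mapping, excluded = genotype_barcode_groups(
        dna_co, cell_variants, params, truth.annotation
    )
    statuses = pd.Series([g.status for g in consensus.values()])
    eligible = [g for g in consensus.values() if g.reason != "too_few_cells"]
    report["genotyping"] = {
        "n_groups": len(groups),
        "n_groups_min_cells": len(eligible),
        "n_callable": int((statuses != "uncallable").sum()),
        "n_wt": int((statuses == "WT").sum()),
        "n_edited": int((statuses == "edited").sum()),
        "n_excluded_cells": len(excluded),
    }

    truth_eval = _evaluate_consensus_against_truth(consensus, truth, params)
    report["genotyping_vs_truth"] = truth_eval

    # --- concordance with gRNA-based predictions
    records = _prediction_concordance(consensus, truth, params)
    if records:
        report["prediction_concordance"] = concordance_summary(records)

    if not include_expression:
        return report

    # --- RNA modality
    logger.info("calling RNA barcodes")
    rna_co, rna_details = call_all_barcodes(
        rna_bc, min_count=config.min_count, p_lo=config.p_lo, p_hi=config.p_hi,
        seed=config.seed, fits=fits,
    )
    expr, qc_report = qc_filter(
        rna_expr, mad_multiplier=config.analysis.qc_mad_multiplier
    )
    report["rna_qc"] = qc_report
    kept = set(expr.cell_ids)
    rna_co_kept = rna_co[rna_co["cell_id"].isin(kept)]

    cell_grna = {
        r.cell_id: r.grna
        for r in rna_co_kept.itertuples(index=False)
        if r.unique_grna_ibar
    }
    nt_grnas = set(
        truth.grna_library.loc[~truth.grna_library["targeting"], "grna_id"]
    )
    logger.info("embedding and clustering transcriptomes")
    embedding = select_features_and_embed(
        expr, cell_grna, nt_grnas, truth.signature_genes,
        params=config.analysis, seed=config.seed,
    )
    clusters = cluster_and_merge(
        embedding, {c: cell_grna.get(c) in nt_grnas for c in expr.cell_ids},
        n_neighbors=config.analysis.n_neighbors,
    )
    nt_cells = [c for c in expr.cell_ids if cell_grna.get(c) in nt_grnas]
    diffusion = diffusion_score(
        embedding, nt_cells, n_neighbors=config.analysis.n_neighbors,
        bridge_components=True,
    )

    logger.info("linking genotypes to transcriptomes")
    linked, unlinked = link_rna_to_genotype(rna_co_kept, consensus, mapping)
    report["linkage"] = {
        "n_rna_cells_assigned": int(rna_co_kept["unique_grna_ibar"].sum()),
        "n_linked": len(linked),
        "n_unlinked": len(unlinked),
    }

    # barcode-level classification anchored on called genotypes
    cell_group = dict(zip(linked["cell_id"], linked["group_id"]))
    cons_of = {g.group_id: g.consequence for g in consensus.values()}
    wt_groups = [gid for gid, c in cons_of.items() if c == "WT"]
    stop_groups = [gid for gid, c in cons_of.items() if c == "stop_gained"]
    if not stop_groups:  # anchor on splice groups when no stop codon is called
        stop_groups = [gid for gid, c in cons_of.items() if c == "splice"]
    linked_scores = diffusion.scores[
        [c in cell_group for c in diffusion.scores.index]
    ]
    classes = classify_barcodes(
        linked_scores, cell_group, wt_groups, stop_groups, params=config.analysis
    )
    classes["consequence"] = [cons_of.get(b) for b in classes.index]
    classes["phenotype"] = np.where(classes["class"] == "LoF", "LoF", "notLoF")
    report["barcode_classes"] = classes

    eval_report = evaluate_classification(classes)
    report["evaluation"] = {
        "tp": eval_report.tp, "fp": eval_report.fp,
        "fn": eval_report.fn, "tn": eval_report.tn,
    }
    try:
        report["evaluation"]["precision_pct"] = eval_report.precision_pct
        report["evaluation"]["recall_pct"] = eval_report.recall_pct
    except ZeroDivisionError:
        report["evaluation"]["undefined_metrics"] = True

    de_table, lof_grnas = lof_group_de(
        clusters, cell_grna, expr, nt_grnas, params=config.analysis
    )
    report["lof_group"] = {
        "n_lof_grnas": len(lof_grnas),
        "n_significant_genes": int(de_table["significant"].sum())
        if len(de_table) else 0,
    }
    report["_objects"] = {
        "truth": truth, "consensus": consensus, "groups": groups,
        "embedding": embedding, "clusters": clusters, "diffusion": diffusion,
        "classes": classes, "linked": linked, "expr": expr,
        "cell_grna": cell_grna, "nt_grnas": nt_grnas,
        "dna_co": dna_co, "rna_co": rna_co_kept, "mapping": mapping,
        "de_table": de_table,
    }
    return report


def _evaluate_consensus_against_truth(consensus, truth, params) -> dict:
    """Exact-match rate of consensus calls against the simulated truth."""
    truth_by_key = {}
    for row in truth.barcodes.itertuples(index=False):
        truth_by_key[f"{row.grna_id}|{row.ibar}"] = row.barcode_id
    n_eligible = n_callable = n_exact = 0
    for gid, geno in consensus.items():
        barcode_id = truth_by_key.get(gid)
        if barcode_id is None or geno.reason == "too_few_cells":
            continue
        n_eligible += 1
        if geno.status == "uncallable":
            continue
        n_callable += 1
        true_variants = truth.barcode_variants(barcode_id)
        if geno.status == "WT":
            n_exact += not true_variants
        else:
            n_exact += geno.variants == true_variants
    return {
        "n_eligible_groups": n_eligible,
        "n_callable": n_callable,
        "exact_match_rate_callable": n_exact / n_callable if n_callable else np.nan,
        "exact_match_rate_eligible": n_exact / n_eligible if n_eligible else np.nan,
    }


def _prediction_concordance(consensus, truth, params) -> list:
    """compare_to_prediction records for callable targeting groups."""
    lib = truth.grna_library.set_index("grna_id")
    records = []
    for gid, geno in consensus.items():
        if geno.status == "uncallable":
            continue
        grna_id = gid.split("|")[0]
        if grna_id not in lib.index or not lib.loc[grna_id, "targeting"]:
            continue
        row = lib.loc[grna_id]
        rec = GRNARecord(
            grna_id=grna_id, protospacer=row["protospacer"],
            chrom=row["chrom"] or None, start=int(row["start"]),
            strand=row["strand"], targeting=True,
        )
        pred = predict_genotype_from_grna(
            rec, window=truth.config.editing_window,
            ploidy=params.ploidy, annotation=truth.annotation,
        )
        records.append(
            compare_to_prediction(geno, pred, truth.annotation, params)
        )
    return records
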