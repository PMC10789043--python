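"""Reference worked examples at the scale of the original study.

These fixtures encode the published dataset-level counts of the assay the
pipeline was developed on — 12 stop-codon barcode groups (all with a
loss-of-function expression phenotype), 15 splice groups (14 LoF) and 77
WT groups (76 with low scores), and the DNA-modality barcode overlap
counts (13,102 cells with a unique puroR, 10,869 with a unique gRNA+iBAR,
10,112 with both).  Running the evaluation operations on them reproduces
the headline precision/recall and linkage percentages and serves as a
fixed-point check of the reporting arithmetic.
"""

from __future__ import annotations

import pandas as pd

from .containers import EvalReport
from .linkage import LinkageSummary, evaluate_classification, summarize_linkage

#: barcode counts by called consequence and diffusion-score phenotype
REFERENCE_BARCODE_COUNTS = {
    ("stop_gained", "LoF"): 12,
    ("stop_gained", "notLoF"): 0,
    ("splice", "LoF"): 14,
    ("splice", "notLoF"): 1,
    ("WT", "LoF"): 1,
    ("WT", "notLoF"): 76,
}

#: DNA-modality cells by barcode-system assignment
REFERENCE_LINKAGE_COUNTS = {
    "unique_puror": 13_102,
    "unique_grna_ibar": 10_869,
    "both": 10_112,
}


def reference_barcode_table() -> pd.DataFrame:
    """One row per barcode group: called consequence + phenotype class."""
    rows = []
    for (consequence, phenotype), n in REFERENCE_BARCODE_COUNTS.items():
        for i in range(n):
            rows.append((f"{consequence}_{phenotype}_{i}", consequence, phenotype))
    return pd.DataFrame(rows, columns=["barcode", "consequence", "phenotype"])


def reference_co_assignments() -> pd.DataFrame:
    """Per-cell co-assignment flags reproducing the published counts."""
    c = REFERENCE_LINKAGE_COUNTS
    rows = []
    rows += [(f"b{i}", "g", "i", "p") for i in range(c["both"])]
    rows += [
        (f"p{i}", "", "", "p")
        for i in range(c["unique_puror"] - c["both"])
    ]
    rows += [
        (f"g{i}", "g", "i", "")
        for i in range(c["unique_grna_ibar"] - c["both"])
    ]
    df = pd.DataFrame(rows, columns=["cell_id", "grna", "ibar", "puror"])
    df["unique_grna_ibar"] = (df["grna"] != "") & (df["ibar"] != "")
    df["unique_puror"] = df["puror"] != ""
    df["both"] = df["unique_grna_ibar"] & df["unique_puror"]
    return df


def reference_evaluation() -> EvalReport:
    return evaluate_classification(reference_barcode_table())


def reference_linkage_summary() -> LinkageSummary:
    return summarize_linkage(reference_co_assignments())


def reference_class_rates() -> dict:
    """Per-class phenotype rates of the reference table (percent)."""
    table = reference_barcode_table()
    out = {}
    for consequence, expected in (
        ("stop_gained", "LoF"), ("splice", "LoF"), ("WT", "notLoF")
    ):
        sub = table[table["consequence"] == consequence]
        rate = 100.0 * (sub["phenotype"] == expected).mean()
        out[consequence] = rate
    return out
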