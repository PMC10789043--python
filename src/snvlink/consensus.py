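"""Barcode-group consensus genotype calling.

Single-cell genotyping of a near-triploid genome is noisy: per-allele
dropout around 10% and spurious heterozygous calls mean individual cells
cannot be trusted.  Because every transduced parent cell is marked by a
unique barcode combination, its daughter cells form a *barcode group*, and
the genotype is called on the group:

* a variant is called if carried by at least ``min_cells_variant`` cells
  making up at least ``min_fraction`` of the group, at the dosage shared by
  a strict majority of carriers;
* a group is WT if no position has more than ``wt_max_mutated_cells``
  mutated cells (0 for groups below ``small_group_cutoff`` cells);
* anything between is uncallable;
* groups below ``min_group_size`` cells are never genotyped.

Before calling, cell genotypes are restricted to the substitutions a
cytidine base editor can make (C>T on either strand, i.e. C>T / G>A on the
forward strand) and variants recurring across more than
``recurrence_fraction`` of the barcode groups are removed as artifacts not
caused by the gRNAs.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import SEVERITY_RANK, most_severe
from .containers import BarcodeGroup, ConsensusGenotype

JAK1_PROMOTER = ("chr1", 64_964_978, 64_967_543)


@dataclass
class ConsensusParams:
    """Thresholds of the barcode-group genotyping rules."""

    min_cells_variant: int = 2
    min_fraction: float = 0.5
    wt_max_mutated_cells: int = 1
    small_group_cutoff: int = 10
    min_group_size: int = 3
    recurrence_fraction: float = 0.10
    allowed_substitutions: frozenset = frozenset({("C", "T"), ("G", "A")})
    ploidy: int = 3
    promoter_interval: tuple = JAK1_PROMOTER

    def __post_init__(self) -> None:
        if not (0 <= self.min_fraction <= 1 and 0 <= self.recurrence_fraction <= 1):
            raise ValueError("fractions must be in [0, 1]")
        if self.min_cells_variant < 1 or self.min_group_size < 1 or self.ploidy < 1:
            raise ValueError("counts must be positive")
        self.allowed_substitutions = frozenset(
            tuple(s) for s in self.allowed_substitutions
        )

    def wt_tolerance(self, group_size: int) -> int:
        """Mutated cells a WT call tolerates at this group size."""
        if group_size < self.small_group_cutoff:
            return 0
        return self.wt_max_mutated_cells


def map_puror_to_grna_ibar(co_assignments: pd.DataFrame, min_cells: int = 2) -> dict:
    """Map each puroR barcode to its unique gRNA+iBAR partner.

    A puroR is mapped iff, across cells with both barcode systems called,
    it co-occurs with exactly one gRNA+iBAR pair and that pairing is seen
    in at least ``min_cells`` cells.  Input is the frame from
    :func:`snvlink.assign.co_assign`.
    """
    both = co_assignments[co_assignments["both"]]
    pairs = Counter(
        (p, (g, i))
        for p, g, i in zip(both["puror"], both["grna"], both["ibar"])
    )
    by_puror = defaultdict(list)
    for (p, gi), n in pairs.items():
        by_puror[p].append((gi, n))
    mapping = {}
    for p, partners in by_puror.items():
        if len(partners) == 1 and partners[0][1] >= min_cells:
            mapping[p] = partners[0][0]
    return mapping


def form_barcode_groups(
    co_assignments: pd.DataFrame, puror_mapping: dict
) -> tuple[list, pd.DataFrame]:
    """Group cells into clones by their barcode combination.

    Cells with both a gRNA+iBAR and a puroR are keyed by the gRNA+iBAR
    pair; cells with only one barcode system join the group whose key
    matches (via ``puror_mapping`` for puroR-only cells).  Cells whose two
    barcodes map to different groups are excluded and reported.

    Returns ``(groups, excluded)`` where ``excluded`` lists the conflicting
    cells with a reason.
    """
    members = defaultdict(list)   # (grna, ibar) -> cells
    key_puror = {}                # (grna, ibar) -> puroR observed with it
    excluded = []

    for row in co_assignments.itertuples(index=False):
        gi = (row.grna, row.ibar) if row.unique_grna_ibar else None
        pu = row.puror if row.unique_puror else None
        if gi and pu:
            mapped = puror_mapping.get(pu)
            if mapped is not None and mapped != gi:
                excluded.append((row.cell_id, "conflicting_barcodes"))
                continue
            members[gi].append(row.cell_id)
            key_puror.setdefault(gi, pu)
        elif gi:
            members[gi].append(row.cell_id)
        elif pu:
            mapped = puror_mapping.get(pu)
            if mapped is not None:
                members[mapped].append(row.cell_id)
                key_puror.setdefault(mapped, pu)
            else:
                excluded.append((row.cell_id, "unmapped_puror"))
        else:
            excluded.append((row.cell_id, "no_barcode"))

    groups = [
        BarcodeGroup(
            group_id=f"{g}|{i}",
            cell_ids=cells,
            grna_ibar=(g, i),
            puror=key_puror.get((g, i)),
        )
        for (g, i), cells in sorted(members.items())
    ]
    excluded = pd.DataFrame(excluded, columns=["cell_id", "reason"])
    return groups, excluded


def filter_edit_types(table: pd.DataFrame, params: ConsensusParams) -> pd.DataFrame:
    """Keep only rows whose ref>alt substitution the base editor can make."""
    bases = {"A", "C", "G", "T"}
    malformed = (
        ~table["ref"].isin(bases)
        | ~table["alt"].isin(bases)
        | (table["ref"] == table["alt"])
    )
    if malformed.any():
        warnings.warn(
            f"rejecting {int(malformed.sum())} malformed ref/alt rows",
            RuntimeWarning,
        )
        table = table[~malformed]
    keep = [
        (r, a) in params.allowed_substitutions
        for r, a in zip(table["ref"], table["alt"])
    ]
    return table[np.asarray(keep, dtype=bool)].reset_index(drop=True)


def remove_recurrent_artifacts(
    variant_groups: dict, n_groups: int | None = None,
    recurrence_fraction: float = 0.10,
) -> set:
    """Drop variants seen in more than ``recurrence_fraction`` of groups.

    ``variant_groups`` maps variant key (chrom, pos, ref, alt) -> set of
    group ids carrying it (any cell, any dosage).  Returns the retained
    variant keys; the strict ``>`` matches the rule that a variant at
    exactly the cutoff is kept.
    """
    if n_groups is None:
        all_groups = set()
        for gs in variant_groups.values():
            all_groups |= set(gs)
        n_groups = len(all_groups)
    if n_groups == 0:
        raise ValueError("no barcode groups: cannot compute recurrence")
    return {
        v
        for v, gs in variant_groups.items()
        if len(set(gs)) <= recurrence_fraction * n_groups
    }


def variant_group_incidence(
    table: pd.DataFrame, groups: list
) -> dict:
    """Variant -> set of group ids with at least one carrier cell."""
    cell_group = {}
    for g in groups:
        for c in g.cell_ids:
            cell_group[c] = g.group_id
    incidence = defaultdict(set)
    carriers = table[table["dosage"] > 0]
    for row in carriers.itertuples(index=False):
        gid = cell_group.get(row.cell_id)
        if gid is not None:
            incidence[(row.chrom, row.pos, row.ref, row.alt)].add(gid)
    return dict(incidence)


def _zygosity(variants, ploidy: int) -> str:
    dosages = {d for *_, d in variants}
    if len(dosages) > 1:
        return "mixed"
    (d,) = dosages
    if d == ploidy:
        return "homozygous"
    return f"het{d}"


def call_consensus(
    group: BarcodeGroup, table: pd.DataFrame, params: ConsensusParams
) -> ConsensusGenotype:
    """Call the consensus genotype of one barcode group.

    ``table`` is the (edit-type- and recurrence-filtered) per-cell variant
    table.  See the module docstring for the calling rules; dosage is the
    strictly most common value among carrier cells, and a dosage tie makes
    the group uncallable (conservative).
    """
    n = group.size
    if n < params.min_group_size:
        return ConsensusGenotype(
            group.group_id, "uncallable", reason="too_few_cells", n_cells=n
        )
    cells = set(group.cell_ids)
    sub = table[table["cell_id"].isin(cells) & (table["dosage"] > 0)]

    by_variant = defaultdict(list)
    for row in sub.itertuples(index=False):
        by_variant[(row.chrom, row.pos, row.ref, row.alt)].append(int(row.dosage))

    called = []
    wt_ok = True
    uncallable_reason = None
    for variant in sorted(by_variant):
        dosages = by_variant[variant]
        m = len(dosages)
        if m > params.wt_tolerance(n):
            wt_ok = False
        if m >= params.min_cells_variant and m >= params.min_fraction * n:
            counts = Counter(dosages).most_common()
            top_dosage, top_n = counts[0]
            if top_n * 2 <= m:  # no strict majority of carriers (incl. ties)
                uncallable_reason = "no_dosage_majority"
                continue
            called.append((*variant, top_dosage))
        elif m >= params.min_cells_variant:
            # carried by >= 2 cells but under 50% of the group: neither
            # callable nor compatible with WT
            uncallable_reason = uncallable_reason or "below_call_threshold"
        # m below min_cells_variant (a lone mutated cell) only affects wt_ok

    if uncallable_reason is not None:
        return ConsensusGenotype(
            group.group_id, "uncallable", reason=uncallable_reason, n_cells=n
        )
    if called:
        return ConsensusGenotype(
            group.group_id,
            "edited",
            variants=called,
            zygosity=_zygosity(called, params.ploidy),
            n_cells=n,
        )
    if wt_ok:
        return ConsensusGenotype(group.group_id, "WT", n_cells=n)
    return ConsensusGenotype(
        group.group_id, "uncallable", reason="not_wt_not_called", n_cells=n
    )


def assign_consequence(
    genotype: ConsensusGenotype,
    annotation: dict,
    params: ConsensusParams,
) -> ConsensusGenotype:
    """Attach the most severe homozygous consequence to a callable genotype.

    ``annotation`` maps (chrom, pos, ref, alt) -> consequence class.  A
    called variant inside the promoter interval needs no annotation entry;
    any other unannotated variant raises.  Only homozygous variants
    (dosage == ploidy) contribute; a genotype with only heterozygous edits
    gets consequence ``none (heterozygous)``.
    """
    if genotype.status == "uncallable":
        return genotype
    if genotype.status == "WT":
        genotype.consequence = "WT"
        return genotype

    chrom_p, start_p, end_p = params.promoter_interval
    consequences = []
    missing = []
    for chrom, pos, ref, alt, dosage in genotype.variants:
        if dosage != params.ploidy:
            continue
        key = (chrom, pos, ref, alt)
        if key in annotation:
            c = annotation[key]
            if c not in SEVERITY_RANK:
                raise ValueError(f"unknown consequence {c!r} for {key}")
        elif chrom == chrom_p and start_p <= pos <= end_p:
            c = "promoter"
        else:
            missing.append(key)
            continue
        consequences.append(c)
    if missing:
        raise ValueError(f"unannotated variants outside promoter: {missing}")
    genotype.consequence = most_severe(consequences) or "none (heterozygous)"
    return genotype


@dataclass
class GRNARecord:
    """Library metadata for one gRNA."""

    grna_id: str
    protospacer: str            # 5'->3' on the protospacer strand
    chrom: str | None = None
    start: int | None = None    # genomic position of protospacer base 1
    strand: str = "+"
    targeting: bool = True


@dataclass
class PredictedGenotype:
    """Genotype predicted from the gRNA assuming complete window editing."""

    grna_id: str
    variants: list = field(default_factory=list)  # (chrom, pos, ref, alt, dosage)
    window: tuple = (4, 8)
    non_targeting: bool = False
    consequence: str | None = None


def predict_genotype_from_grna(
    grna: GRNARecord,
    window: tuple = (4, 8),
    ploidy: int = 3,
    annotation: dict | None = None,
) -> PredictedGenotype:
    """Predict the edit assuming every window cytosine is fully converted.

    Protospacer positions ``window[0]..window[1]`` (1-based, PAM-distal)
    carrying a C are predicted edited to T on all alleles; coordinates are
    reported on the genomic forward strand (C>T for '+' guides, G>A for
    '-' guides).  Non-targeting guides predict WT.
    """
    if grna.targeting is False or grna.chrom is None:
        return PredictedGenotype(grna.grna_id, window=window, non_targeting=True)
    lo, hi = window
    if not (1 <= lo <= hi <= len(grna.protospacer)):
        raise ValueError(
            f"window {window} outside protospacer of length {len(grna.protospacer)}"
        )
    variants = []
    for i in range(lo, hi + 1):
        if grna.protospacer[i - 1] != "C":
            continue
        if grna.strand == "+":
            pos, ref, alt = grna.start + (i - 1), "C", "T"
        else:
            pos, ref, alt = grna.start - (i - 1), "G", "A"
        variants.append((grna.chrom, pos, ref, alt, ploidy))
    pred = PredictedGenotype(grna.grna_id, variants=sorted(variants), window=window)
    if annotation is not None:
        pred.consequence = (
            most_severe(
                annotation[(c, p, r, a)]
                for c, p, r, a, _ in pred.variants
                if (c, p, r, a) in annotation
            )
            or "WT"
        )
    return pred


def compare_to_prediction(
    called: ConsensusGenotype,
    predicted: PredictedGenotype,
    annotation: dict,
    params: ConsensusParams,
) -> dict:
    """Concordance of a called genotype with its gRNA-based prediction.

    Returns nucleotide-level concordance (the homozygous edit set exactly
    matches the predicted one), protein-level concordance (same functional
    consequence class), and a discordance reason in
    ``heterozygous | unedited | different_consequence``.
    """
    called_hom = sorted(
        (c, p, r, a) for c, p, r, a, d in called.variants if d == params.ploidy
    )
    predicted_set = sorted((c, p, r, a) for c, p, r, a, _ in predicted.variants)
    nucleotide = called_hom == predicted_set and called.status != "uncallable"

    if called.consequence in (None, "WT", "none (heterozygous)"):
        called_cons = "WT"
    else:
        called_cons = called.consequence
    pred_cons = predicted.consequence
    if pred_cons is None:
        pred_cons = (
            most_severe(
                annotation[(c, p, r, a)]
                for c, p, r, a in predicted_set
                if (c, p, r, a) in annotation
            )
            or "WT"
        )
    protein = called_cons == pred_cons

    reason = None
    if not protein:
        if called.status == "edited" and not called_hom:
            reason = "heterozygous"
        elif called.status == "WT" or (
            called.status == "edited" and not called.variants
        ):
            reason = "unedited"
        else:
            reason = "different_consequence"
    return {
        "grna_id": predicted.grna_id,
        "group_id": called.group_id,
        "nucleotide_match": bool(nucleotide),
        "protein_match": bool(protein),
        "called_consequence": called_cons,
        "predicted_consequence": pred_cons,
        "discordance_reason": reason,
    }
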