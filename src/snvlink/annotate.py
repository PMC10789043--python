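"""Variant consequence annotation against a toy transcript model.

Full annotation of real screens is expected to come in as a precomputed
variant -> consequence table (e.g. from VEP restricted to MANE select
transcripts).  For synthetic data, and for small real panels, this module
provides a minimal single-transcript annotator: a forward- or
reverse-strand gene with exons and a CDS, against which an SNV is
classified as stop_gained / start_lost / splice / missense / synonymous /
intron / promoter by codon translation.

The severity ranking used to pick a barcode group's dominant consequence is

    stop_gained/start_lost > splice > missense > promoter/intron > synonymous

and only homozygous edits (dosage == ploidy) are considered, as
heterozygous edits are not expected to have a strong functional
consequence in this assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

#: consequence classes ordered most-severe first
SEVERITY_ORDER = (
    "stop_gained",
    "start_lost",
    "splice",
    "missense",
    "promoter",
    "intron",
    "synonymous",
)

#: rank (lower = more severe); stop_gained and start_lost tie at the top,
#: promoter and intron tie per the reporting convention
SEVERITY_RANK = {
    "stop_gained": 0,
    "start_lost": 0,
    "splice": 1,
    "missense": 2,
    "promoter": 3,
    "intron": 3,
    "synonymous": 4,
}

SPLICE_REGION = 2  # bp of intron adjacent to an exon boundary


@dataclass
class ToyGeneModel:
    """Single-transcript gene model on one chromosome (1-based, inclusive).

    ``exons`` are (start, end) pairs in genomic order; the CDS is the
    concatenation of exon sequence (reverse-complemented for '-' strand)
    and must start with ATG.  ``promoter`` is an optional (start, end)
    interval labelled ``promoter``.
    """

    chrom: str
    sequence: str            # full contig sequence, 1-based indexing via pos-1
    exons: list = field(default_factory=list)
    strand: str = "+"
    promoter: tuple | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        self.exons = sorted(tuple(e) for e in self.exons)
        for s, e in self.exons:
            if not (1 <= s <= e <= len(self.sequence)):
                raise ValueError(f"exon ({s},{e}) outside contig")

    def base(self, pos: int) -> str:
        return self.sequence[pos - 1]

    def _cds_positions(self) -> list:
        """Genomic positions of CDS bases in translation order (cached)."""
        if not hasattr(self, "_cds_pos_cache"):
            pos = [p for s, e in self.exons for p in range(s, e + 1)]
            self._cds_pos_cache = pos[::-1] if self.strand == "-" else pos
            self._cds_index_cache = {p: i for i, p in enumerate(self._cds_pos_cache)}
        return self._cds_pos_cache

    def _cds_index(self, pos: int) -> int:
        self._cds_positions()
        return self._cds_index_cache[pos]

    def cds(self) -> str:
        if not hasattr(self, "_cds_cache"):
            bases = [self.base(p) for p in self._cds_positions()]
            seq = "".join(bases)
            if self.strand == "-":
                seq = str(Seq(seq).complement())
            self._cds_cache = seq
        return self._cds_cache

    def classify(self, pos: int, ref: str, alt: str) -> str:
        """Consequence class of an SNV on this model."""
        if self.base(pos) != ref:
            raise ValueError(
                f"{self.chrom}:{pos} reference is {self.base(pos)}, not {ref}"
            )
        if self.promoter and self.promoter[0] <= pos <= self.promoter[1]:
            return "promoter"
        in_exon = any(s <= pos <= e for s, e in self.exons)
        if not in_exon:
            near_junction = any(
                0 < s - pos <= SPLICE_REGION or 0 < pos - e <= SPLICE_REGION
                for s, e in self.exons
            )
            if near_junction:
                return "splice"
            lo = min(s for s, _ in self.exons)
            hi = max(e for _, e in self.exons)
            if lo <= pos <= hi:
                return "intron"
            return "intron"  # flanking UTR-less model: treat as intergenic/intron
        cds_pos = self._cds_index(pos)
        cds = self.cds()
        alt_base = alt if self.strand == "+" else str(Seq(alt).complement())
        codon_i = cds_pos // 3
        codon = cds[3 * codon_i: 3 * codon_i + 3]
        if len(codon) < 3:
            return "synonymous"  # trailing partial codon
        mutant = list(codon)
        mutant[cds_pos % 3] = alt_base
        mutant = "".join(mutant)
        aa_ref = str(Seq(codon).translate())
        aa_alt = str(Seq(mutant).translate())
        if codon_i == 0 and aa_ref == "M" and aa_alt != "M":
            return "start_lost"
        if aa_alt == "*" and aa_ref != "*":
            return "stop_gained"
        if aa_alt == aa_ref:
            return "synonymous"
        return "missense"


def most_severe(consequences) -> str | None:
    """Most severe class under the ranking, or None for an empty list."""
    consequences = list(consequences)
    if not consequences:
        return None
    unknown = [c for c in consequences if c not in SEVERITY_RANK]
    if unknown:
        raise ValueError(f"unknown consequence classes: {unknown}")
    return min(consequences, key=lambda c: (SEVERITY_RANK[c], c))


def build_annotation_table(model: ToyGeneModel, variants) -> dict:
    """Annotate an iterable of (chrom, pos, ref, alt) against the model.

    Returns a dict keyed by the variant tuple.  Variants on other
    chromosomes raise.
    """
    out = {}
    for chrom, pos, ref, alt in variants:
        if chrom != model.chrom:
            raise ValueError(f"variant on {chrom} but model covers {model.chrom}")
        out[(chrom, pos, ref, alt)] = model.classify(pos, ref, alt)
    return out
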