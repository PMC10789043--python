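"""Synthetic coupled scDNA + scRNA screen generator with known truth.

The generator emulates the statistical structure the pipeline assumes:

* a lentivirally barcoded base-editor screen in a triploid line — every
  transduced parent cell carries a unique iBAR and puroR barcode plus one
  gRNA, and its daughter cells form a barcode group;
* targeted single-cell genotyping with ~10% per-allele dropout, spurious
  heterozygous calls, and a few recurrent artifact sites shared across
  barcodes;
* barcode UMI counts drawn from a 3-component skew-normal mixture on the
  log scale (one ambient background mode, two signal modes);
* a transcriptome with a baseline (wild-type / non-targeting) state and a
  loss-of-function state shifted in a set of signature genes, plus
  separation-of-function clones whose cells respond stochastically.

gRNA target sites are sampled on a toy single-transcript gene so that the
consequence of complete editing in the protospacer window (stop, splice,
missense, synonymous, intron, promoter) is known exactly, and per-barcode
editing outcomes (unedited / heterozygous / homozygous, complete or
partial window) determine the true genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import skewnorm

from .annotate import ToyGeneModel, most_severe
from .consensus import GRNARecord, predict_genotype_from_grna
from .containers import CountMatrix, VARIANT_COLUMNS

LOF_PHENOTYPES = ("notLoF", "LoF", "SoF")


@dataclass
class AmbientMixture:
    """3-component skew-normal mixture of log UMI counts.

    Component 0 is ambient background; components 1 and 2 are signal.
    """

    weights: tuple = (0.50, 0.30, 0.20)
    locations: tuple = (1.1, 4.0, 5.3)
    scales: tuple = (0.55, 0.50, 0.40)
    alphas: tuple = (2.0, -2.0, -2.0)

    def __post_init__(self) -> None:
        for f in (self.weights, self.locations, self.scales, self.alphas):
            if len(f) != 3:
                raise ValueError("ambient mixture must have exactly 3 components")
        if abs(sum(self.weights) - 1.0) > 1e-8:
            raise ValueError("mixture weights must sum to 1")
        if any(s <= 0 for s in self.scales):
            raise ValueError("mixture scales must be positive")

    def draw_counts(self, rng, component: int, size: int) -> np.ndarray:
        """Integer UMI counts from one component (>= 1)."""
        x = skewnorm.rvs(
            self.alphas[component],
            loc=self.locations[component],
            scale=self.scales[component],
            size=size,
            random_state=rng,
        )
        return np.maximum(np.rint(np.exp(x)).astype(np.int64), 1)

    def draw_signal(self, rng, size: int) -> np.ndarray:
        """Signal counts: component 1 or 2, by renormalised weights."""
        w1, w2 = self.weights[1], self.weights[2]
        comp = 1 + (rng.random(size) < w2 / (w1 + w2)).astype(int)
        out = np.empty(size, dtype=np.int64)
        for k in (1, 2):
            mask = comp == k
            out[mask] = self.draw_counts(rng, k, int(mask.sum()))
        return out


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic screen.

    Defaults are the conditions the assay was designed around: clones
    genotyped across ~10 cells and phenotyped across ~50 cells, a triploid
    genome, ~10% allele dropout, and a screen of 250 barcodes over 2,000
    genes.
    """

    n_barcodes: int = 250
    frac_nt: float = 0.12                  # barcodes carrying non-targeting gRNAs
    cells_per_barcode_dna: float = 10.0    # Poisson mean, truncated >= 1
    cells_per_barcode_rna: float = 50.0
    ploidy: int = 3
    dropout_rate: float = 0.10             # per-allele miss probability
    het_noise_rate: float = 0.02           # per cell per noise site spurious het
    n_noise_sites: int = 30                # shared pool of spurious-het sites
    recurrent_artifact_sites: int = 2
    recurrent_artifact_rate: float = 0.30  # per-cell rate at artifact sites
    #: editing outcome per targeting barcode
    genotype_class_probs: dict = field(
        default_factory=lambda: {"WT": 0.20, "het1": 0.20, "het2": 0.10, "hom": 0.50}
    )
    hom_complete_prob: float = 0.9         # hom clones editing the full window
    #: predicted-consequence mix of targeting gRNA sites
    consequence_class_probs: dict = field(
        default_factory=lambda: {
            "stop_gained": 0.14, "splice": 0.10, "missense": 0.40,
            "synonymous": 0.16, "intron": 0.10, "promoter": 0.10,
        }
    )
    #: phenotype of a homozygous-missense clone
    missense_phenotype_probs: dict = field(
        default_factory=lambda: {"notLoF": 0.45, "LoF": 0.35, "SoF": 0.20}
    )
    sof_responder_prob: float = 0.5
    sof_intermediate_prob: float = 0.2   # non-responders with a partial effect
    sof_intermediate_scale: float = 0.5  # fraction of the full LoF effect
    n_genes: int = 2000
    n_signature_genes: int = 100
    lof_logfc: np.ndarray | None = None    # natural-log effects, default +/-log 2.5
    nb_dispersion: float = 10.0
    libsize_sigma: float = 0.10
    ambient_mixture: AmbientMixture = field(default_factory=AmbientMixture)
    p_ambient: float = 0.02                # foreign-barcode ambient probability
    editing_window: tuple = (4, 8)
    grna_sharing: float = 0.10             # fraction of barcodes reusing a gRNA
    doublet_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frac_nt", "dropout_rate", "het_noise_rate", "hom_complete_prob",
            "sof_responder_prob", "sof_intermediate_prob",
            "sof_intermediate_scale", "p_ambient", "recurrent_artifact_rate",
            "grna_sharing", "doublet_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_barcodes", "ploidy", "n_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_signature_genes > self.n_genes:
            raise ValueError("n_signature_genes exceeds n_genes")
        for name in ("genotype_class_probs", "consequence_class_probs",
                     "missense_phenotype_probs"):
            p = getattr(self, name)
            if abs(sum(p.values()) - 1.0) > 1e-8 or min(p.values()) < 0:
                raise ValueError(f"{name} must be a probability distribution")
        if self.lof_logfc is None:
            signs = np.where(np.arange(self.n_signature_genes) % 2 == 0, -1.0, 1.0)
            self.lof_logfc = signs * np.log(2.5)
        self.lof_logfc = np.asarray(self.lof_logfc, dtype=float)
        if self.lof_logfc.shape != (self.n_signature_genes,):
            raise ValueError(
                f"lof_logfc length {self.lof_logfc.size} != "
                f"n_signature_genes {self.n_signature_genes}"
            )


@dataclass
class TrueScreen:
    """Ground truth of a simulated screen."""

    barcodes: pd.DataFrame      # barcode_id, grna_id, ibar, puror, outcome,
                                # consequence, phenotype
    variants: pd.DataFrame      # barcode_id, chrom, pos, ref, alt, dosage
    cells_dna: pd.DataFrame     # cell_id, barcode_id
    cells_rna: pd.DataFrame     # cell_id, barcode_id, responder, state
    grna_library: pd.DataFrame  # grna_id, protospacer, chrom, start, strand, targeting
    annotation: dict            # (chrom, pos, ref, alt) -> consequence
    gene_model: ToyGeneModel
    noise_sites: list           # (chrom, pos, ref, alt) spurious-het pool
    artifact_sites: list        # (chrom, pos, ref, alt) recurrent artifacts
    gene_ids: list
    signature_genes: list
    config: SimConfig

    def barcode_variants(self, barcode_id: str) -> list:
        sub = self.variants[self.variants["barcode_id"] == barcode_id]
        return sorted(
            (r.chrom, r.pos, r.ref, r.alt, int(r.dosage))
            for r in sub.itertuples(index=False)
        )


# ---------------------------------------------------------------------------
# toy genome / gene model


def build_toy_gene(rng) -> ToyGeneModel:
    """Random single-transcript forward-strand gene on a 9 kb contig.

    Promoter at 701..1000, six 252 bp exons from 1001 separated by 700 bp
    introns; the CDS is forced to start with ATG and internal stop codons
    are recoded so that stop-gained edits are unambiguous.
    """
    length = 9000
    seq = rng.choice(list("ACGT"), size=length, p=[0.25, 0.25, 0.25, 0.25])
    exons = []
    pos = 1001
    for _ in range(6):
        exons.append((pos, pos + 251))
        pos += 252 + 700
    seq[1000:1003] = list("ATG")  # start codon at CDS base 1
    model = ToyGeneModel(
        chrom="chr1", sequence="".join(seq), exons=exons,
        strand="+", promoter=(701, 1000),
    )
    # recode premature stops (TAA/TAG/TGA) to CAA/CAG/CGA
    cds_pos = model._cds_positions()
    s = list(model.sequence)
    for i in range(1, len(cds_pos) // 3):
        codon = "".join(s[p - 1] for p in cds_pos[3 * i: 3 * i + 3])
        if codon in ("TAA", "TAG", "TGA"):
            s[cds_pos[3 * i] - 1] = "C"
    return ToyGeneModel(
        chrom="chr1", sequence="".join(s), exons=exons,
        strand="+", promoter=(701, 1000),
    )


def _revcomp(s: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[b] for b in reversed(s))


def enumerate_target_sites(model: ToyGeneModel, window=(4, 8), proto_len=20):
    """All candidate protospacers with >= 1 window C, bucketed by the
    predicted consequence of complete window editing."""
    seq = model.sequence
    lo, hi = window
    buckets: dict[str, list] = {}
    records = {}
    for strand in "+-":
        for start in range(1, len(seq) - proto_len + 1):
            if strand == "+":
                proto = seq[start - 1: start - 1 + proto_len]
                genomic_start = start
            else:
                proto = _revcomp(seq[start - 1: start - 1 + proto_len])
                genomic_start = start + proto_len - 1
            window_cs = [i for i in range(lo, hi + 1) if proto[i - 1] == "C"]
            if not window_cs:
                continue
            rec = GRNARecord(
                grna_id="", protospacer=proto, chrom=model.chrom,
                start=genomic_start, strand=strand, targeting=True,
            )
            pred = predict_genotype_from_grna(rec, window=window)
            cons = most_severe(
                model.classify(p, r, a) for _, p, r, a, _ in pred.variants
            )
            buckets.setdefault(cons, []).append((strand, genomic_start))
            records[(strand, genomic_start)] = rec
    return buckets, records


def _sample_grna_sites(rng, buckets, records, n_grnas, class_probs):
    """Sample distinct target sites to match the consequence-class mix."""
    classes = list(class_probs)
    want = rng.multinomial(n_grnas, [class_probs[c] for c in classes])
    chosen = []
    shortfall = 0
    for c, k in zip(classes, want):
        pool = buckets.get(c, [])
        take = min(k, len(pool))
        shortfall += k - take
        idx = rng.choice(len(pool), size=take, replace=False)
        chosen += [pool[i] for i in idx]
    if shortfall:
        spare = [
            s for c in ("missense", "synonymous") for s in buckets.get(c, [])
            if s not in set(chosen)
        ]
        idx = rng.choice(len(spare), size=shortfall, replace=False)
        chosen += [spare[i] for i in idx]
    return [records[key] for key in chosen]


# ---------------------------------------------------------------------------
# truth assembly


def _truncated_poisson(rng, mean: float, size: int) -> np.ndarray:
    """Poisson(mean) conditioned on >= 1 (by resampling zeros)."""
    out = rng.poisson(mean, size=size)
    while (out == 0).any():
        zeros = out == 0
        out[zeros] = rng.poisson(mean, size=int(zeros.sum()))
    return out


def _build_truth(config: SimConfig, rng) -> TrueScreen:
    model = build_toy_gene(rng)
    window = config.editing_window
    buckets, records = enumerate_target_sites(model, window=window)

    n_nt_barcodes = int(round(config.frac_nt * config.n_barcodes))
    n_targeting_barcodes = config.n_barcodes - n_nt_barcodes
    n_grnas = max(1, int(round((1 - config.grna_sharing) * n_targeting_barcodes)))
    grnas = _sample_grna_sites(
        rng, buckets, records, n_grnas, config.consequence_class_probs
    )
    for i, g in enumerate(grnas):
        g.grna_id = f"g{i + 1:04d}"
    n_nt_grnas = max(2, n_nt_barcodes // 4) if n_nt_barcodes else 0
    nt_grnas = [
        GRNARecord(
            grna_id=f"NT{i + 1:02d}",
            protospacer="".join(rng.choice(list("ACGT"), size=20)),
            targeting=False,
        )
        for i in range(n_nt_grnas)
    ]
    library = pd.DataFrame(
        [
            (g.grna_id, g.protospacer, g.chrom or "", g.start or 0, g.strand,
             g.targeting)
            for g in grnas + nt_grnas
        ],
        columns=["grna_id", "protospacer", "chrom", "start", "strand", "targeting"],
    )

    # barcode -> gRNA (distinct first, then reuse for sharing)
    barcode_grnas = []
    for b in range(n_targeting_barcodes):
        if b < n_grnas:
            barcode_grnas.append(grnas[b])
        else:
            barcode_grnas.append(grnas[int(rng.integers(n_grnas))])
    for b in range(n_nt_barcodes):
        barcode_grnas.append(nt_grnas[int(rng.integers(n_nt_grnas))])

    outcome_classes = list(config.genotype_class_probs)
    outcome_p = [config.genotype_class_probs[c] for c in outcome_classes]

    rows, variant_rows = [], []
    annotation = {}
    for b, grna in enumerate(barcode_grnas):
        barcode_id = f"bc{b + 1:04d}"
        ibar = f"iBAR{b + 1:04d}"
        puror = f"pR{b + 1:04d}"
        if not grna.targeting:
            outcome, variants = "NT", []
        else:
            outcome = outcome_classes[
                int(rng.choice(len(outcome_classes), p=outcome_p))
            ]
            pred = predict_genotype_from_grna(
                grna, window=window, ploidy=config.ploidy
            )
            edits = [(c, p, r, a) for c, p, r, a, _ in pred.variants]
            if outcome == "WT" or not edits:
                variants = []
            else:
                if outcome == "hom" and rng.random() > config.hom_complete_prob:
                    k = int(rng.integers(1, len(edits))) if len(edits) > 1 else 1
                    idx = sorted(rng.choice(len(edits), size=k, replace=False))
                    edits = [edits[i] for i in idx]
                dosage = {"het1": 1, "het2": 2, "hom": config.ploidy}[outcome]
                variants = [(c, p, r, a, dosage) for c, p, r, a in edits]
        for c, p, r, a, d in variants:
            if (c, p, r, a) not in annotation:
                annotation[(c, p, r, a)] = model.classify(p, r, a)
            variant_rows.append((barcode_id, c, p, r, a, d))
        hom_cons = [
            annotation[(c, p, r, a)]
            for c, p, r, a, d in variants
            if d == config.ploidy
        ]
        consequence = most_severe(hom_cons) or (
            "WT" if not variants else "none (heterozygous)"
        )
        if consequence in ("stop_gained", "start_lost", "splice"):
            phenotype = "LoF"
        elif consequence == "missense":
            classes = list(config.missense_phenotype_probs)
            phenotype = classes[int(rng.choice(
                len(classes), p=[config.missense_phenotype_probs[c] for c in classes]
            ))]
        else:
            phenotype = "notLoF"
        rows.append(
            (barcode_id, grna.grna_id, ibar, puror, outcome, consequence, phenotype)
        )

    barcodes = pd.DataFrame(
        rows,
        columns=["barcode_id", "grna_id", "ibar", "puror", "outcome",
                 "consequence", "phenotype"],
    )
    variants = pd.DataFrame(
        variant_rows, columns=["barcode_id", "chrom", "pos", "ref", "alt", "dosage"]
    )

    # spurious-het site pool and recurrent artifact sites: editable C/G sites
    # away from any true target site
    used = set(zip(variants["pos"], variants["ref"])) if len(variants) else set()
    candidates = [
        p for p in range(1, len(model.sequence) + 1)
        if model.sequence[p - 1] in "CG" and (p, model.sequence[p - 1]) not in used
    ]
    pick = rng.choice(
        len(candidates),
        size=config.n_noise_sites + config.recurrent_artifact_sites,
        replace=False,
    )
    sites = []
    for i in pick:
        p = candidates[i]
        ref = model.sequence[p - 1]
        alt = "T" if ref == "C" else "A"
        sites.append((model.chrom, p, ref, alt))
    noise_sites = sites[: config.n_noise_sites]
    artifact_sites = sites[config.n_noise_sites:]

    # cells
    dna_sizes = _truncated_poisson(rng, config.cells_per_barcode_dna,
                                   config.n_barcodes)
    rna_sizes = _truncated_poisson(rng, config.cells_per_barcode_rna,
                                   config.n_barcodes)
    cells_dna = pd.DataFrame(
        [
            (f"d{j + 1:05d}", barcodes.loc[b, "barcode_id"])
            for j, b in enumerate(np.repeat(np.arange(config.n_barcodes), dna_sizes))
        ],
        columns=["cell_id", "barcode_id"],
    )
    rna_barcode_idx = np.repeat(np.arange(config.n_barcodes), rna_sizes)
    phenotype_by_idx = barcodes["phenotype"].to_numpy()
    responder = rng.random(rna_barcode_idx.size) < config.sof_responder_prob
    states = []
    for j, b in enumerate(rna_barcode_idx):
        ph = phenotype_by_idx[b]
        if ph == "LoF":
            states.append("lof")
        elif ph == "SoF":
            # responders react to stimulation like wild type; non-responders
            # look like loss of function, a few with a partial effect
            if responder[j]:
                states.append("baseline")
            elif rng.random() < config.sof_intermediate_prob:
                states.append("intermediate")
            else:
                states.append("lof")
        else:
            states.append("baseline")
    cells_rna = pd.DataFrame(
        {
            "cell_id": [f"r{j + 1:05d}" for j in range(rna_barcode_idx.size)],
            "barcode_id": barcodes["barcode_id"].to_numpy()[rna_barcode_idx],
            "responder": responder,
            "state": states,
        }
    )

    gene_ids = [f"gene{g + 1:04d}" for g in range(config.n_genes)]
    signature = gene_ids[: config.n_signature_genes]
    return TrueScreen(
        barcodes=barcodes, variants=variants, cells_dna=cells_dna,
        cells_rna=cells_rna, grna_library=library, annotation=annotation,
        gene_model=model, noise_sites=noise_sites,
        artifact_sites=artifact_sites, gene_ids=gene_ids,
        signature_genes=signature, config=config,
    )


# ---------------------------------------------------------------------------
# observation models


def simulate_cell_genotypes(
    truth: TrueScreen, dropout_rate: float, het_noise_rate: float, seed: int
) -> pd.DataFrame:
    """Observed per-cell variant table of the DNA modality.

    Each true allele is observed independently with probability
    ``1 - dropout_rate`` (a cell's observed dosage is Binomial); spurious
    dosage-1 calls are injected at ``het_noise_rate`` per cell per noise
    site, and at the elevated artifact rate at recurrent artifact sites.
    """
    if not 0 <= dropout_rate <= 1 or not 0 <= het_noise_rate <= 1:
        raise ValueError("dropout_rate and het_noise_rate must be in [0, 1]")
    if len(truth.cells_dna) == 0:
        raise ValueError("truth contains no DNA cells")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    var_by_barcode = {
        b: g.drop(columns="barcode_id")
        for b, g in truth.variants.groupby("barcode_id")
    }
    rows = []
    for cell_id, barcode_id in truth.cells_dna.itertuples(index=False):
        sub = var_by_barcode.get(barcode_id)
        if sub is not None:
            for chrom, pos, ref, alt, dosage in sub.itertuples(index=False):
                observed = int(rng.binomial(dosage, 1 - dropout_rate))
                if observed > 0:
                    rows.append((cell_id, chrom, pos, ref, alt, observed))
        for chrom, pos, ref, alt in truth.noise_sites:
            if rng.random() < het_noise_rate:
                rows.append((cell_id, chrom, pos, ref, alt, 1))
        for chrom, pos, ref, alt in truth.artifact_sites:
            if rng.random() < truth.config.recurrent_artifact_rate:
                rows.append((cell_id, chrom, pos, ref, alt, 1))
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def simulate_barcode_counts(
    truth: TrueScreen,
    ambient_mixture: AmbientMixture,
    seed: int,
    modality: str = "dna",
    p_ambient: float | None = None,
) -> CountMatrix:
    """UMI counts for the gRNA / iBAR / puroR classes of one modality.

    Every cell receives one signal draw for each of its own barcode's three
    features and ambient draws for a Binomial(n_barcodes, p_ambient) subset
    of foreign barcodes per class.
    """
    if p_ambient is None:
        p_ambient = truth.config.p_ambient
    cells = truth.cells_dna if modality == "dna" else truth.cells_rna
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, 202 if modality == "dna" else 203])
    )
    barcodes = truth.barcodes.set_index("barcode_id")
    grna_ids = list(truth.grna_library["grna_id"])
    ibar_ids = list(truth.barcodes["ibar"])
    puror_ids = list(truth.barcodes["puror"])
    feature_ids = grna_ids + ibar_ids + puror_ids
    feature_classes = (
        ["gRNA"] * len(grna_ids) + ["iBAR"] * len(ibar_ids)
        + ["puroR"] * len(puror_ids)
    )
    col = {f: j for j, f in enumerate(feature_ids)}
    class_features = {
        "gRNA": grna_ids, "iBAR": ibar_ids, "puroR": puror_ids,
    }

    n_cells = len(cells)
    own = barcodes.loc[cells["barcode_id"], ["grna_id", "ibar", "puror"]]
    ri, ci, data = [], [], []
    for cls, own_col in (("gRNA", "grna_id"), ("iBAR", "ibar"), ("puroR", "puror")):
        own_features = own[own_col].to_numpy()
        signal = ambient_mixture.draw_signal(rng, n_cells)
        feats = class_features[cls]
        n_feats = len(feats)
        for i in range(n_cells):
            ri.append(i)
            ci.append(col[own_features[i]])
            data.append(signal[i])
            n_amb = rng.binomial(n_feats - 1, p_ambient)
            if n_amb:
                others = rng.choice(n_feats, size=n_amb, replace=False)
                amb_counts = ambient_mixture.draw_counts(rng, 0, n_amb)
                for j, c in zip(others, amb_counts):
                    f = feats[j]
                    if f == own_features[i]:
                        continue
                    ri.append(i)
                    ci.append(col[f])
                    data.append(c)
    matrix = sp.coo_matrix(
        (data, (ri, ci)), shape=(n_cells, len(feature_ids)), dtype=np.int64
    ).tocsr()
    matrix.sum_duplicates()
    return CountMatrix(
        matrix, cells["cell_id"].to_numpy(), feature_ids, feature_classes
    )


def simulate_expression(truth: TrueScreen, config: SimConfig, seed: int) -> CountMatrix:
    """Negative-binomial gene counts for the RNA cells.

    Gene means are log-normal; signature genes are shifted by
    ``lof_logfc`` in cells whose true state is ``lof`` (LoF clones and SoF
    non-responders).  Counts are Gamma-Poisson with dispersion
    ``nb_dispersion`` and a mild log-normal library-size factor.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    n_sig = config.n_signature_genes
    log_mu = np.empty(config.n_genes)
    log_mu[:n_sig] = rng.normal(2.0, 0.3, size=n_sig)
    log_mu[n_sig:] = rng.normal(0.0, 1.0, size=config.n_genes - n_sig)
    mu_base = np.exp(log_mu)
    mu_lof = mu_base.copy()
    mu_lof[:n_sig] = mu_base[:n_sig] * np.exp(config.lof_logfc)
    mu_mid = mu_base.copy()
    mu_mid[:n_sig] = mu_base[:n_sig] * np.exp(
        config.sof_intermediate_scale * config.lof_logfc
    )

    states = truth.cells_rna["state"].to_numpy()
    n_cells = len(states)
    libsize = np.exp(rng.normal(0.0, config.libsize_sigma, size=n_cells))
    counts = np.empty((n_cells, config.n_genes), dtype=np.int64)
    theta = config.nb_dispersion
    chunk = 2000
    for start in range(0, n_cells, chunk):
        end = min(start + chunk, n_cells)
        st = states[start:end]
        mu = np.where(
            (st == "lof")[:, None], mu_lof[None, :],
            np.where((st == "intermediate")[:, None], mu_mid[None, :],
                     mu_base[None, :]),
        ) * libsize[start:end, None]
        lam = rng.gamma(theta, mu / theta)
        counts[start:end] = rng.poisson(lam)
    return CountMatrix(
        sp.csr_matrix(counts),
        truth.cells_rna["cell_id"].to_numpy(),
        truth.gene_ids,
        ["gene"] * config.n_genes,
    )


def generate_screen(config: SimConfig):
    """Generate a full coupled screen.

    Returns ``(truth, cell_variants, rna_expression, dna_barcode_counts,
    rna_barcode_counts)``; all five outputs are deterministic given
    ``config.seed`` and mutually consistent with the truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    truth = _build_truth(config, rng)
    cell_variants = simulate_cell_genotypes(
        truth, config.dropout_rate, config.het_noise_rate, config.seed
    )
    rna_expr = simulate_expression(truth, config, config.seed)
    dna_bc = simulate_barcode_counts(
        truth, config.ambient_mixture, config.seed, modality="dna"
    )
    rna_bc = simulate_barcode_counts(
        truth, config.ambient_mixture, config.seed, modality="rna"
    )
    return truth, cell_variants, rna_expr, dna_bc, rna_bc
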