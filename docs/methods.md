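# Methods

This note documents the models and numerical choices behind `snvlink`,
what the synthetic data do and do not emulate, and the limitations a user
should keep in mind.

## Barcode-count mixture model

Pooled UMI counts of one barcode class (all gRNAs of a modality together,
likewise iBARs and puroR barcodes) are modeled as a three-component
mixture of skew-normal distributions of the log count: one component for
ambient background molecules and two for genuine ("signal") expression,
allowing for a bimodal signal distribution. Counts at or below
`min_count = 2` are discarded before fitting.

**Discreteness.** Low UMI counts are coarse on the log scale (log 3 to
log 4 is a 0.29 gap), and a continuous density can raise its likelihood
without bound by collapsing a component onto a single integer value. The
likelihood is therefore the *interval* (rounded) form,
P(c) = F(log(c+1/2)) − F(log(c−1/2)), with F the skew-normal CDF computed
via Owen's T function. This is also the exact law of a rounded
log-skew-normal draw, which is how the simulator generates counts. For
speed, counts ≤ 64 get exact integer bins and larger counts geometric
bins (ratio 1.1); the interval probability is exact for every bin.

**EM.** The E-step computes component responsibilities on the bin grid.
The M-step updates the weights in closed form and each component's
(ξ, log ω, α) by Nelder–Mead on its weighted bin likelihood, with an
explicit initial simplex (step 1.0 in α, without which a zero-initialised
skewness never moves), |α| capped at 25 (beyond which the density is
numerically half-normal) and ω bounded in [0.05, 2·SD]. Any update that
would lower the observed likelihood is rejected, so the likelihood is
non-decreasing by construction (a generalized EM). Initialisation places
components at the count terciles (moment-matched) with two further
deterministic and three random restarts; the best likelihood wins. On
20,000 counts from a known mixture the fit recovers locations to well
within 10% and weights within 0.05.

**Thresholds.** P(ambient | count) is evaluated on the integer grid from
`min_count + 1` to the largest observed count. `t_lo` is the last count
before the posterior first drops below 0.9; `t_hi` is the largest count
whose posterior exceeds 0.1 (the most conservative crossing if the
posterior is non-monotone). With no ambient mass both collapse to
`min_count` — every count is signal — and a fit whose ambient posterior
never reaches 0.1 raises an error rather than silently assigning nothing.
When the data genuinely contain no ambient mode (the simulator's
noise-free limit), a three-component fit is unidentifiable; simulation
studies pass the generating parameters directly instead of fitting.

## Consensus genotyping

The genotype of a clone is called from its barcode group, not from single
cells, because single-cell genotyping of a triploid genome drops ~10% of
alleles and produces spurious heterozygous calls. The rules, in order:

1. restrict to substitutions a cytidine editor can produce — C>T or G>A
   on the genomic forward strand (configurable);
2. remove variants carried by more than 10% of barcode groups (strictly
   greater), which recur far too often to be gRNA-induced;
3. for each group of n ≥ 3 cells and each variant with m carrier cells:
   called if m ≥ 2 and m ≥ 0.5·n, at the dosage shared by a strict
   majority of carriers (a tie or absent majority makes the group
   uncallable); a variant with 2 ≤ m < 0.5·n also makes the group
   uncallable; a single mutated cell blocks a WT call only in groups of
   fewer than 10 cells (larger groups tolerate one);
4. the group is WT when every site passes the WT rule, edited when at
   least one variant is called, uncallable otherwise; groups under 3
   cells are reported but never genotyped.

The denominator n is all cells of the group, not cells with coverage at
the site. Consequences are assigned to homozygous (dosage = ploidy)
variants only — heterozygous edits are not expected to have strong
functional effects in this assay — ranked stop/start-lost > splice >
missense > promoter/intron > synonymous, with a configurable promoter
interval (default the JAK1 promoter, chr1:64,964,978–64,967,543).

With 10-cell groups and 10% dropout, the strict-majority dosage rule
makes roughly 10% of homozygous calls uncallable (the majority of
carriers must show all three alleles); these go to `uncallable` rather
than to a wrong dosage, which is the intended conservative trade-off.

**Predicted genotypes.** The genotype expected from a gRNA alone assumes
complete conversion of every protospacer cytosine in the editing window
(default positions 4–8, standard for this editor class; the window is
configurable), homozygous, mapped to forward-strand coordinates (C>T for
+ guides, G>A for − guides). Concordance of called vs predicted genotypes
is reported at nucleotide and protein level with discordance reasons
(heterozygous / unedited / different consequence).

## Transcriptome analysis

Expression is library-size normalised to the median and log1p
transformed. Differential expression is non-parametric throughout: the
two-sample Wilcoxon rank-sum test with mid-rank ties, reported as
AUC = U/(n_A·n_B) (probability that a random cell of A exceeds a random
cell of B), asymptotic tie-corrected p-values and Benjamini–Hochberg
adjustment at FDR 0.1. Cells sharing a clone need not respond equally —
stochastic SoF clones are the extreme — so no parametric count model is
assumed.

QC removes low outliers of log total counts and log detected features and
high outliers of mitochondrial percentage, at median ± 3 MAD (vacuous
when no mitochondrial genes are flagged). The embedding is PCA (20
components, deterministic sign convention) over the union of genes DE for
at least one gRNA with ≥ 10 cells versus non-targeting cells plus a
pathway/signature gene list; the non-targeting reference is subsampled to
500 cells (seeded) in these per-gRNA scans to bound cost. Louvain
clustering (igraph's multilevel modularity) runs on the 10-NN graph of
the embedding with cells sorted by id first, making the partition
order-invariant; fine clusters are merged to exactly two meta-clusters by
average-linkage hierarchical clustering of centroids, and the meta-cluster
with the higher non-targeting percentage is notLoF.

**Diffusion score.** A Gaussian kernel with per-cell adaptive bandwidth
(distance to the k-th neighbor, k = 10) on the kNN graph is
density-normalised (α = 1) and symmetrised; the first non-trivial
eigenvector of the normalised operator is the score, oriented so
reference (NT/WT) cells score low, min–max scaled to [0, 1]. Identical
embedding coordinates are collapsed before the eigensolve and the scores
broadcast back, so duplicate cells share scores exactly; the Lanczos
start vector is fixed to the constant vector for run-to-run determinism.
A disconnected kernel graph raises by default; the pipeline passes
`bridge_components=True`, adding one floor-weight edge between each
component and its nearest neighbor component so the operator is
irreducible while between-state transitions stay rare. (A perfectly
separated two-state population is an artifact of simulation; real
populations connect through intermediate cells.)

**Clone classification.** Clone (barcode) classes are anchored on called
genotypes: the notLoF bound is the 95th percentile of WT-clone mean
scores and the LoF bound the 5th percentile of stop-codon-clone mean
scores, computed with `method='higher'` / `'lower'` so that at the small
reference counts typical of a screen the anchors sit on observed values
(with ≤ 20 stop clones the LoF bound is their minimum). Crossing anchors
raise an error. Sarle's bimodality coefficient of per-cell scores is
reported per clone; elevated values in intermediate clones indicate a
stochastic (SoF) response. For the stop/splice-vs-WT audit, a clone's
phenotype is LoF iff its class is LoF.

## Linkage

RNA cells with a gRNA+iBAR (or a puroR mapped to one through cells
carrying both systems in ≥ 2 cells) inherit the consensus genotype of the
matching barcode group; cells of uncallable groups are reported as
unlinked. Label transfer to a reference dataset uses a deliberately
simple joint embedding — per-gene centering of each dataset, then joint
PCA — as a stand-in for mutual-nearest-neighbour correction; any
externally corrected embedding can be supplied. Each query cell takes the
coordinates of its nearest reference cell and the modal label of its 10
nearest reference neighbors, distance ties broken by cell id and modal
ties toward the nearer label. Cells that are the lone representative of
their clone within a cluster are dropped as probable barcode
misassignments.

## Synthetic data

The generator's defaults are the study conditions the assay targets:
250 clones, clone sizes Poisson (truncated ≥ 1) with mean 10 for the DNA
modality and 50 for the RNA modality, ploidy 3, allele dropout 0.10,
spurious het rate 0.02 per cell per noise site over a shared pool of 30
sites plus 2 recurrent artifact sites at rate 0.30, 12% non-targeting
clones, 2,000 genes with 100 signature genes shifted ±log 2.5 in the LoF
state, negative-binomial counts (dispersion 10, log-normal library sizes,
σ = 0.1), and barcode counts from the 3-component skew-normal mixture
(ambient ξ = 1.1, signal ξ = 4.0 and 5.3 on the log scale) with each cell
receiving ambient draws for a Binomial(n_barcodes, 0.02) subset of
foreign barcodes.

Editing outcomes per targeting clone are unedited 20% / het1 20% / het2
10% / homozygous 50%, homozygous clones editing the complete window with
probability 0.9; gRNA sites are sampled from an enumerated toy gene model
(9 kb contig, promoter, six exons) so that stop, splice, missense,
synonymous, intron and promoter consequences arise with a realistic mix
and are known exactly. Homozygous-missense clones are benign 45% / LoF
35% / SoF 20%; a SoF cell responds to stimulation normally with
probability 0.5, otherwise it expresses the LoF state (20% of
non-responders at half effect, giving the intermediate cells real
populations have). Spurious het sites are shared across clones, which is
precisely why the >10% recurrence filter removes them — the same
mechanism the real pipeline relies on.

What the simulation does *not* emulate: read-level errors and chemistry
(PCR, sequencing error profiles), doublets (beyond an optional fraction
flag, default 0), ambient *gene* expression, batch effects between
modalities, and continuous transcriptional heterogeneity beyond the
three-state (baseline / intermediate / LoF) model. Passing tests
therefore demonstrate that the *algorithms* recover a known truth under
the stated noise model, not that the noise model captures every property
of real screens.

## Problem sizes and determinism

The default end-to-end study runs 250 clones / ~2,400 DNA cells /
~12,400 RNA cells / 2,000 genes and completes in about one to two
minutes on one CPU; unit tests use 25–60-clone screens. All stochastic
steps take seeds derived from a single entry point
(`numpy.random.SeedSequence`), and identical configuration plus seed
yields bit-identical outputs.

## Known limitations

- The skew-normal mixture is fitted per barcode class pooled over all
  features; strongly feature-specific count distributions would violate
  the pooling assumption.
- The strict-majority dosage rule is conservative by design; with few
  cells per clone it converts borderline homozygous calls into
  uncallable rather than guessing.
- The joint embedding used for label transfer is not a batch-correction
  method; with strong batch effects supply a corrected embedding.
- The toy transcript annotator handles a single transcript model with
  SNVs only (no indels, no UTR semantics beyond the promoter interval);
  real screens should supply a VEP-style annotation table.
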