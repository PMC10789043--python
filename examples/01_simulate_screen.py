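"""Generate a small synthetic coupled screen and look at its ground truth.

The generator builds a toy gene model, samples gRNA target sites by the
consequence of complete window editing, assigns every clone (barcode) an
editing outcome and phenotype, and emits the four observed datasets:
per-cell variant calls, barcode UMI counts for both modalities, and a
gene expression matrix.
"""

from snvlink import SimConfig, generate_screen

config = SimConfig(
    n_barcodes=50, cells_per_barcode_rna=20,
    n_genes=500, n_signature_genes=50, seed=7,
)
truth, cell_variants, rna_expr, dna_bc, rna_bc = generate_screen(config)

print(f"{config.n_barcodes} barcodes -> "
      f"{len(truth.cells_dna)} DNA cells, {len(truth.cells_rna)} RNA cells")
print("\nEditing outcome per clone (unedited / het / hom):")
print(truth.barcodes["outcome"].value_counts().to_string())
print("\nTrue consequence classes:")
print(truth.barcodes["consequence"].value_counts().to_string())
print("\nPhenotypes (notLoF / LoF / stochastic SoF):")
print(truth.barcodes["phenotype"].value_counts().to_string())
print(f"\nObserved per-cell variant rows: {len(cell_variants)} "
      f"(includes ~10% allele dropout and spurious het calls)")
print(f"Expression matrix: {rna_expr.matrix.shape[0]} cells x "
      f"{rna_expr.matrix.shape[1]} genes")
# The truth tables are what every later stage is scored against.
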