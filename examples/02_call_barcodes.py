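"""Fit the 3-component skew-normal count mixture and assign barcodes.

Pooled UMI counts of one barcode class mix an ambient background mode
with two signal modes.  The EM fit identifies them on the log scale; the
ambient posterior then yields two count thresholds, and a barcode is
called in a cell only when it clears the upper threshold while every
other barcode stays at or below the lower one.
"""

import numpy as np

from snvlink import SimConfig, generate_screen
from snvlink.pipeline import call_barcode_class

config = SimConfig(n_barcodes=50, cells_per_barcode_rna=20,
                   n_genes=100, n_signature_genes=10, seed=7)
truth, _, _, dna_bc, _ = generate_screen(config)

table, fit, thresholds = call_barcode_class(dna_bc, "gRNA", seed=7)

print("Fitted components (log-count scale):")
for k in range(3):
    tag = " <- ambient" if k == fit.ambient_component_index else ""
    print(f"  pi={fit.weights[k]:.2f}  xi={fit.locations[k]:.2f}  "
          f"omega={fit.scales[k]:.2f}  alpha={fit.skews[k]:+.1f}{tag}")
print(f"\nThresholds: t_lo={thresholds.t_lo} (90% ambient posterior), "
      f"t_hi={thresholds.t_hi} (10% ambient posterior)")
print("\nAssignment outcome per cell:")
print(table.table["reason"].value_counts().to_string())

# accuracy against the simulation truth
truth_grna = truth.barcodes.set_index("barcode_id")["grna_id"]
cell_barcode = truth.cells_dna.set_index("cell_id")["barcode_id"]
assigned = table.assigned
correct = np.mean([
    f == truth_grna[cell_barcode[c]]
    for c, f in zip(assigned["cell_id"], assigned["feature_id"])
])
print(f"\nPrecision of unique assignments vs truth: {100 * correct:.1f}%")
# Cells with a second barcode above t_lo stay unassigned (ambiguous) —
# that rule is also what removes doublets carrying two gRNAs.
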