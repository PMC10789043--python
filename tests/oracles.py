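"""Independent brute-force reference implementations used as test oracles.

Each function re-implements a pipeline rule with plain loops, staying
deliberately independent of the package code paths it checks.
"""

from collections import Counter

import numpy as np


def consensus_oracle(cell_variants: dict, n_cells: int, min_group_size=3,
                     small_cutoff=10):
    """Barcode-group genotype call by direct application of the rules.

    ``cell_variants`` maps cell id -> {variant key: dosage > 0}.  Returns
    (status, {variant: dosage}) with status WT / edited / uncallable.
    """
    if n_cells < min_group_size:
        return "uncallable", {}
    carriers = {}
    for _, muts in cell_variants.items():
        for v, d in muts.items():
            carriers.setdefault(v, []).append(d)
    wt_tol = 1 if n_cells >= small_cutoff else 0
    called = {}
    any_uncallable = False
    blocks_wt = False
    for v, dosages in carriers.items():
        m = len(dosages)
        if m > wt_tol:
            blocks_wt = True
        if m >= 2 and m >= 0.5 * n_cells:
            top, top_n = Counter(dosages).most_common(1)[0]
            if top_n * 2 > m:
                called[v] = top
            else:
                any_uncallable = True
        elif m >= 2:
            any_uncallable = True
    if any_uncallable:
        return "uncallable", {}
    if called:
        return "edited", called
    if not blocks_wt:
        return "WT", {}
    return "uncallable", {}


def auc_oracle(a, b):
    """Two-sample AUC by exhaustive pairwise comparison (ties count 1/2)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    wins = 0.0
    for x in a:
        for y in b:
            if x > y:
                wins += 1.0
            elif x == y:
                wins += 0.5
    return wins / (len(a) * len(b))


def knn_transfer_oracle(ref_coords, ref_ids, ref_labels, query_coords, k):
    """k-NN majority label transfer by exhaustive distance computation.

    Distance ties break by reference cell id; modal-label ties break
    toward the label whose member appears earliest in the neighbor list.
    """
    ref_coords = np.asarray(ref_coords, float)
    out = []
    for q in np.asarray(query_coords, float):
        d = np.sqrt(((ref_coords - q) ** 2).sum(axis=1))
        order = sorted(range(len(ref_ids)), key=lambda i: (d[i], str(ref_ids[i])))
        neighbors = order[:k]
        labels = [ref_labels[ref_ids[i]] for i in neighbors]
        counts = Counter(labels)
        top_n = max(counts.values())
        tied = {lab for lab, c in counts.items() if c == top_n}
        if len(tied) == 1:
            out.append(tied.pop())
        else:
            first = {}
            for rank, lab in enumerate(labels):
                if lab in tied and lab not in first:
                    first[lab] = rank
            out.append(min(first, key=lambda lab: (first[lab], str(lab))))
    return out


def threshold_oracle(fit, p_lo, p_hi, grid_max):
    """Dual thresholds by evaluating the posterior at every integer."""
    grid = np.arange(fit.min_count + 1, grid_max + 1)
    post = fit.posterior_ambient(grid)
    above_hi = [int(c) for c, p in zip(grid, post) if p > p_hi]
    t_hi = above_hi[-1] if above_hi else fit.min_count
    below_lo = [int(c) for c, p in zip(grid, post) if p < p_lo]
    if not below_lo:
        t_lo = t_hi
    elif below_lo[0] == grid[0]:
        t_lo = fit.min_count
    else:
        t_lo = below_lo[0] - 1
    return min(t_lo, t_hi), t_hi
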