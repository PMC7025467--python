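"""Fit a drift tree plus one migration edge and read off the evidence.

Simulates allele frequencies from a six-population graph with a known
migration (t1 -> t3, weight 0.4), fits the tree, inspects residuals,
adds a migration edge and compares the fits.
"""

import numpy as np

from admixkit.graphfit import (
    add_migration_edges,
    covariance_matrix,
    fit_tree,
    predicted_covariance,
    scaled_residuals,
    tree_fit_report,
)
from admixkit.simdata import (
    SimSpec,
    sample_allele_freqs,
    simulate_frequencies,
    six_tip_migration_scenario,
)

graph, true_edge, w_true = six_tip_migration_scenario(w=0.4)
spec = SimSpec(graph=graph, n_snps=5000, samples_per_pop=20, seed=5)
freqs, snp_map, _ = simulate_frequencies(spec)
table = sample_allele_freqs(freqs, spec, snp_map)

cov = covariance_matrix(table, block=20)
tree = fit_tree(cov, outgroup="out", n_searches=2, seed=0)[0][0]
base = tree_fit_report(tree, cov)
print("fitted tree:", tree.newick(lengths=False))
print(f"variance explained (tree only): {base.variance_explained:.4f}")

R = scaled_residuals(cov.W, predicted_covariance(tree, cov.populations),
                     cov.SE)
i, j = np.unravel_index(np.argmax(R - np.diag(np.diag(R))), R.shape)
print(f"largest positive residual: {cov.populations[i]} / "
      f"{cov.populations[j]} at {R[i, j]:.2f} SE  "
      "(underfitted relatedness -> migration candidate)")

report = add_migration_edges(tree, cov, m=1, seed=0)
info = report.migrations[0]
print(f"\nvariance explained (with 1 edge): "
      f"{report.variance_explained:.4f}")
print(f"edge: {sorted(info.origin_tips)} -> {sorted(info.dest_tips)} "
      f"(truth: {sorted(true_edge[0])} -> {sorted(true_edge[1])})")
print(f"weight {info.weight:.3f} (truth {w_true}), jackknife SE "
      f"{info.se:.3f}, p = {info.p:.2e}")
# A significant weight with the correct clades means the block-jackknife
# evidence for gene flow survives resampling of the genome.
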