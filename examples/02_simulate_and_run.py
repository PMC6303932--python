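"""Simulate one modular-DE replicate and recover the module.

Generates a scale-free network of 200 genes, plants a coherent 20-gene
module (10% DE, effect half-range d=8), samples 32 log-expression profiles
from the matched Gaussian graphical model, and runs both the coherent
procedure and the network-naive baseline.  The printed metrics show the
coherence filter buying precision at a small sensitivity cost.
"""

from cone import (
    DEPatternConfig,
    DesignSpec,
    GraphConfig,
    baseline_de_subnetwork,
    run_cone,
    simulate_dataset,
    subnetwork_metrics,
)

dataset = simulate_dataset(
    GraphConfig(family="scale_free_ba", v=200, m=2),
    DEPatternConfig(pattern="modular", fraction=0.10, n_modules=1, d=8.0),
    n=32,
    seed=20240901,
)
truth = dataset.truth
print(f"simulated: {truth.network.n_genes} genes, {truth.network.n_links} links, "
      f"inducing fraction p={truth.inducing_proportion:.3f}")
print(f"truth module: {truth.truth_subnetwork.n_genes} genes, "
      f"{truth.truth_subnetwork.n_links} coherent links")

design = DesignSpec.two_group(dataset.class_labels)
result = run_cone(dataset.expression, truth.network, design, alpha=0.05)
baseline = baseline_de_subnetwork(truth.network, result.gene_stats, alpha=0.05)

print(f"\ncoherent estimate: {result.subnetwork.n_genes} genes, "
      f"{result.subnetwork.n_links} links")
print("removed per step:", result.removal_counts())

for name, estimate in (("cone", result.subnetwork), ("baseline", baseline)):
    ms = subnetwork_metrics(truth.truth_subnetwork, estimate, truth.network)
    print(f"{name:>8}: SE_genes={ms.se_genes:.2f} SP_genes={ms.sp_genes:.3f} "
          f"PR_genes={ms.pr_genes:.2f} SE_links={ms.se_links:.2f} "
          f"PR_links={ms.pr_links:.2f}")
# PR (precision) near 1 for the coherent procedure is the point: what it
# reports is almost entirely inside the true module.
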