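"""Calling a factor's regulatory sign from peak-to-TSS distances.

Knockdown differential expression defines a decreased and an increased
gene set; the one-sided Kolmogorov-Smirnov test asks whether each set's
nearest-peak distances are stochastically smaller than background.
"""

import chipexpr as ce

# a planted activator: bound genes drop after knockdown, nothing rises
cfg = ce.SyntheticConfig(seed=7, repressor_effect=0.0)
ds = ce.generate(cfg, include_genome=False, include_coverage=False)

results = ce.run_de(ds.expression, alpha=0.001)
decreased, increased = ce.de_sets(results, 0.001, use_adjusted=False)
distances = ce.nearest_peak_distance(ds.genes, ds.peaks["TF_A"])
expressed = ce.expressed_genes(ds.expression, 6.0)

calls = ce.call_factor_direction(decreased, increased, distances,
                                 expressed - decreased - increased,
                                 alpha=0.01)
for label, call in calls["calls"].items():
    print(f"{label}: n={call.n_set}, D+={call.d_plus:.3f}, p={call.p:.3g}")
print("labels:", calls["labels"])

# D+ is the maximum excess of the gene set's distance ECDF over the
# background's; p = exp(-2 * n_eff * D+^2). Only the decreased set is
# significantly closer to the peaks, so the factor is labelled with
# activator evidence alone — exactly what was planted.
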