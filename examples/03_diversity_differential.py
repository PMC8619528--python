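"""Alpha diversity and differential activity, dose versus control.

Chao1 (bias-corrected richness) and Shannon (nats) per sample, compared
across doses with Kruskal-Wallis → Dunn → Benjamini-Hochberg; then the
per-ASV differential-activity statistic (median-of-ratios normalisation,
pseudocounted log2 fold change, Wilcoxon rank-sum, BH) for the midgut at
0.1 ppb.
"""

import gutnetdys as g
from gutnetdys.diversity import diversity_comparisons

config = g.SynthConfig(seed=42)
design = g.generate_design(config)
table = g.generate_activity(design, config)

div = g.alpha_diversity(table)
print("alpha diversity (first 3 samples):")
print(div.head(3).to_string(index=False))

comp = diversity_comparisons(div, design, metric="shannon")
print("\nShannon, dose comparisons (pooled sections):")
print(comp[["comparison", "dunn_z", "p_raw", "p_bh"]].to_string(index=False))

res = g.diff_activity(table, design, "midgut", 0.1)
print(f"\nmidgut 0.1 ppb vs control: {len(res)} ASVs tested, "
      f"{int(res['significant'].sum())} significant (adjusted p < 0.05)")
cols = ["asv_id", "log2fc", "p_raw", "p_adj", "direction"]
print("strongest shifts:")
print(res.sort_values("p_raw")[cols].head(6).to_string(index=False))
# negative log2 fold changes mark taxa whose transcriptional activity is
# depressed by exposure (the planted Frischella depletion shows up here);
# at n = 10 per arm, rank-sum p-values rarely survive BH across ~30 ASVs,
# so effect sizes carry most of the information

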