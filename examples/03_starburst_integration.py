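"""Starburst integration of methylation and expression calls.

Runs the coupled simulation (coupling = -1: genes with a hypermethylated
planted probe get a -1 log2FC), calls both omics, pairs CpG probes to genes
through shared symbols and classifies each pair into the two starburst
tiers.
"""

import kinoforge as kf

cfg = kf.SimulationConfig(seed=1)
betas, annotations, truth_m = kf.simulate_methylome(cfg)
expr, probe_gene_map, _, _ = kf.simulate_expression_and_qpcr(
    cfg, methylome_truth=truth_m, annotations=annotations
)

dmps = kf.call_dmps(betas)
records = kf.differential_expression(expr)
cpg_gene = annotations.loc[annotations["gene"] != "", ["probe_id", "gene"]]
pairs, unmatched = kf.pair_probes_to_genes(dmps, records, cpg_gene)
classified = kf.classify_pairs(pairs)

counts = kf.tier_counts(classified)
print(f"pairs: {counts['total']}, blue tier: {counts['blue']}, "
      f"red tier: {counts['red']}")
red = classified[classified["tier"] == "red"]
print(f"red pairs in hyper-methylated/down-regulated quadrant: "
      f"{int(((red['x'] < 0) & (red['y'] > 0)).sum())} of {len(red)}")
print("\nfirst red-tier pairs:")
print(red.head(5)[["cpg_probe", "gene", "logfc", "expr_fdr", "delta_beta",
                   "meth_fdr", "x", "y"]].to_string(index=False))
# x = sign(logFC) * -log10(expression FDR); y = sign(delta-beta) *
# -log10(methylation FDR).  Blue needs joint FDR significance; red
# additionally needs |delta-beta| > 0.05 and |logFC| > 0.4.  With
# anti-coupling, red pairs should sit in the x<0, y>0 quadrant.
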