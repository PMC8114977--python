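"""ddCt quantification of a synthetic triplicate qPCR panel.

Three target genes are planted at a 2-fold induction (logFC = 1) against an
ACTB reference in three paired treated/solvent replicates, with per-sample
global Ct offsets that the reference normalization must remove.
"""

import kinoforge as kf

cfg = kf.SimulationConfig(seed=1)
_, _, ct_table, truth = kf.simulate_expression_and_qpcr(cfg)
results = kf.quantify(ct_table, reference_gene="ACTB")

print(results.to_string(index=False))
# logFC = -ddCt (median triplicate Ct, ACTB-normalized, solvent-referenced,
# paired by replicate): each target should recover ~1.0 (2-fold up) with a
# paired t-test p-value across the three replicate pairs.
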