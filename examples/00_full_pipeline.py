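"""Full pipeline run on synthetic inputs with a reproducibility manifest.

Executes simulate -> kinome -> express -> dmp -> enrich -> integrate ->
qpcr, writing one TSV per stage plus manifest.json (seed, thresholds and
SHA-256 of every artifact) under ./pipeline_demo/.
"""

import json

import kinoforge as kf

cfg = kf.PipelineConfig(outdir="pipeline_demo", seed=1, permutations=200)
manifest = kf.run_pipeline(cfg)

print("stages run:", ", ".join(manifest["stages_run"]))
print("artifacts:")
for name, entry in manifest["artifacts"].items():
    print(f"  {name}: {entry['path']} (sha256 {entry['sha256'][:12]}...)")
top = manifest["data"]["kinase_scores"].iloc[0]
print(f"\ntop kinase: {top['kinase_id']} (tau {top['tau']:.2f}, "
      f"combined score {top['combined_score']:.2f}, {top['direction']})")
print("starburst tiers:", json.dumps(kf.tier_counts(manifest["data"]["starburst"])))
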