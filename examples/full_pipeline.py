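"""End-to-end pipeline run on a small simulated cohort.

Simulates a vertex-level cohort in memory, runs every stage (filtering,
signal extraction, coupling, wave detection, motion, cohort statistics),
and writes a reproducible result directory of TSV/JSON files.
"""

import json

from boldwaves import SimConfig
from boldwaves.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(sim=SimConfig(
    n_retained=15, n_excluded_low=2, n_excluded_high=1,
    n_vertices=500, n_runs=2, master_seed=3))

summary = run_pipeline(cfg, out_dir="scratch/example_results")

print("stage log:")
print(json.dumps(summary["log"], indent=2, sort_keys=True))
print("\nheadline statistics:")
for name, res in summary["stats"].items():
    print(f"  {name:32s} p = {res['pvalue']:.4f}")
print(f"\nconfig hash {summary['config_hash']} (re-running with the same "
      "seed reproduces every output byte-for-byte)")
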