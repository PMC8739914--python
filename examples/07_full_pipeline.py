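"""Run every stage end-to-end from one configuration.

Equivalent to `mirnet run-all --seed 5 --outdir scratch/pipeline_demo`.
All thresholds (10 kb cluster gap, 2000 nt promoters, expectation <= 3.0,
energy ratio 0.75, <10/>500 RPM classes, k = 16, +/-1 nt and <= 2
mismatches for conservation, degradome categories {0,1,2}) are config
keys; a rerun with the same config is byte-identical.
"""

import json

from mirnet import PipelineConfig, run_all

cfg = PipelineConfig(seed=5, outdir="scratch/pipeline_demo",
                     n_mirna=15, n_sirna=15, genome_length=500_000,
                     library_depth=30_000, kmeans_k=8)
result = run_all(cfg)

print(json.dumps(result.stats, indent=2, sort_keys=True, default=str))
print("\noutputs:")
for name, path in sorted(result.outputs.items()):
    print(f"  {name}: {path}")
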