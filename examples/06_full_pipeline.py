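"""End-to-end run: generation, preprocessing, both heads, risk fusion.

The physiological head and the pathogenic-factor head each emit a
probability; decisions at tau = 0.327 are fused with AND/OR logic into
{no, low, high} risk.  All artifacts (models, weights, metrics, audit
table) are written to the output directory with a manifest.
"""

import json

from strokerisk import demo_config, run_pipeline

config = demo_config(out_dir="scratch/pipeline_demo", seed=0)
artifacts = run_pipeline(config)

print("test-set metrics per head:")
print(json.dumps(artifacts.manifest["metrics"], indent=2))

audit = artifacts.fused_audit
print("\nfused risk levels on the paired test rows:")
print(audit["risk_level"].value_counts().to_string())
print("\nexample audit rows (head probabilities -> decisions -> fused level):")
print(audit.head(4).round(3).to_string(index=False))
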