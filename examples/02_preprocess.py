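"""Run the preprocessing chain on a cohort with injected missingness.

Implausible values are trimmed to NA, continuous gaps are filled by
chained-equation imputation, missing risk flags default to "absent",
categoricals are ordinal-encoded and continuous columns z-scored.
"""

from strokerisk import AugmentationConfig, assemble_datasets
from strokerisk.preprocess import preprocess_chain
from strokerisk.synth import inject_missingness

cfg = AugmentationConfig(target_negatives=600, target_positives=500,
                         source_positives_physio=120, source_positives_pathogenic=110)
_, factors = assemble_datasets(cfg, seed=0)
damaged = inject_missingness(factors, continuous_rate=0.05, categorical_rate=0.03, seed=1)

processed, encoding, scaler, report = preprocess_chain(damaged, seed=0)

worst = max(report.missing_before.values())
print(f"max continuous missing fraction before imputation: {worst:.3f}")
print(f"values trimmed as implausible/zero-filled: {report.total_trimmed}")
print(f"remaining missing continuous values: "
      f"{processed.frame[processed.continuous_columns].isna().sum().sum()}")
print(f"smoking_status codes: {encoding.maps['smoking_status']}")
print(f"age after z-scoring: mean={processed.frame['age'].mean():.2e}, "
      f"sd={processed.frame['age'].std(ddof=0):.3f}")
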