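"""Train the tabular attention classifier on the pathogenic-factor cohort.

Categorical risk factors become learned token embeddings processed by a
Pre-LN self-attention stack; the numeric stream cross-attends over the
contextual tokens; a 3-linear GELU head emits class probabilities.  The
Lion optimizer trains with cross-entropy until the six validation metrics
clear their thresholds or the epoch budget ends.
"""

from strokerisk import (
    ArchitectureConfig,
    AttentionClassifier,
    AugmentationConfig,
    StoppingThresholds,
    assemble_datasets,
    count_layers,
    split_train_val_test,
    train_model,
)
from strokerisk.pipeline import _feature_blocks
from strokerisk.preprocess import preprocess_chain

cfg = AugmentationConfig(target_negatives=600, target_positives=500,
                         source_positives_physio=120, source_positives_pathogenic=110)
_, factors = assemble_datasets(cfg, seed=0)
split = split_train_val_test(factors, seed=0)
processed, encoding, _, _ = preprocess_chain(factors, fit_rows=split.train_idx, seed=0)
x_num, x_cat, cards, _, _ = _feature_blocks(processed, encoding)
y = processed.labels

arch = ArchitectureConfig(embed_dim=16, n_heads=4)
print(f"architecture: {count_layers(arch)} trainable layers "
      f"({arch.n_self_blocks} self-attention blocks of 3, one cross block, 3-linear head)")

model = AttentionClassifier(x_num.shape[1], cards, arch, seed=0)
result = train_model(
    model,
    x_num[split.train_idx], x_cat[split.train_idx], y[split.train_idx],
    x_num[split.val_idx], x_cat[split.val_idx], y[split.val_idx],
    thresholds=StoppingThresholds(max_epochs=10), lr=1e-3, seed=0,
)

last = result.history[-1]
print(f"stopped early: {result.stopped_early} after {len(result.history)} epochs "
      f"(best-AUC checkpoint from epoch {result.best_epoch})")
print("final validation metrics: "
      + ", ".join(f"{k}={v:.3f}" for k, v in last.items() if k != "epoch" and v is not None))
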