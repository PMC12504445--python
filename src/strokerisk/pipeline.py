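"""End-to-end orchestration: generate -> preprocess -> focal-boost feature
weighting -> attention training (per family) -> optional metaheuristic
tuning -> evaluation -> AND/OR risk fusion.

Every stage receives its own seed derived from the master seed through a
fixed per-stage counter, so adding a stage never reshuffles another
stage's randomness.  All artifacts land in an output directory together
with a manifest (config hash, stage seeds, versions).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .attention import (
    ArchitectureConfig,
    AttentionClassifier,
    StoppingThresholds,
    train_model,
)
from .focal import (
    DecisionRule,
    FeatureWeightState,
    FocalParams,
    apply_weights,
    fit_boosting,
    shap_contributions,
    update_feature_weights,
)
from .fusion import fuse_batch
from .metrics import evaluate_scores, threshold_sweep
from .preprocess import (
    OrdinalEncoding,
    PreprocessReport,
    ScalerState,
    encode_ordinal,
    impute_boolean,
    impute_continuous,
    plausibility_intervals,
    trim_to_interval,
    zscore,
)
from .schema import DEFAULT_REFERENCE_RANGES, CohortTable
from .synth import (
    AugmentationConfig,
    DataSplit,
    assemble_datasets,
    inject_missingness,
    split_train_val_test,
)

# fixed stage-id registry for counter-based seed derivation
STAGE_IDS = {
    "augment": 0,
    "missingness": 1,
    "split_physio": 2,
    "split_factor": 3,
    "preprocess": 4,
    "boost_physio": 5,
    "boost_factor": 6,
    "attention_physio": 7,
    "attention_factor": 8,
    "swo": 9,
}


def stage_seed(master_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence(master_seed, spawn_key=(STAGE_IDS[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "artifacts"
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    missing_continuous_rate: float = 0.03
    missing_categorical_rate: float = 0.02
    split_ratios: tuple = (7, 2, 1)
    tau: float = 0.327
    focal: FocalParams = field(default_factory=FocalParams)
    boost_rounds: int = 80
    weight_epochs: int = 3
    weight_damping: float = 0.3
    weights_feed_attention: bool = True
    architecture: ArchitectureConfig = field(default_factory=lambda: ArchitectureConfig(embed_dim=16, n_heads=4))
    thresholds: StoppingThresholds = field(default_factory=lambda: StoppingThresholds(max_epochs=15))
    attention_lr: float = 1e-3
    attention_batch: int = 128
    swo_enabled: bool = False
    swo_budget_generations: int = 5
    swo_population: int = 8

    def config_hash(self) -> str:
        def default(o):
            if hasattr(o, "__dict__"):
                return o.__dict__
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        payload = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class FamilyArtifacts:
    """Everything fitted for one feature family."""

    family: str
    split: DataSplit
    intervals: dict
    encoding: OrdinalEncoding
    scaler: ScalerState
    train_medians: dict
    weight_state: FeatureWeightState
    boost_model: object
    attention_model: AttentionClassifier
    report: PreprocessReport
    metrics_test: dict
    sweep: pd.DataFrame


@dataclass
class PipelineArtifacts:
    config: PipelineConfig
    physio: FamilyArtifacts
    factor: FamilyArtifacts
    fused_audit: pd.DataFrame
    manifest: dict


# --------------------------------------------------------------------------
# per-family fitting
# --------------------------------------------------------------------------


def _fit_preprocess(table: CohortTable, seed: int):
    """Fit the preprocessing chain on a training table; return the
    transformed table plus reusable state (encoding, scaler, medians)."""
    intervals = plausibility_intervals(table, DEFAULT_REFERENCE_RANGES)
    table, report = trim_to_interval(table, intervals)
    table, report = impute_continuous(table, intervals, seed=seed, report=report)
    table = impute_boolean(table)
    medians = {c: float(table.frame[c].median()) for c in table.continuous_columns}
    table, encoding = encode_ordinal(table, None, report)
    table, scaler = zscore(table)
    return table, intervals, encoding, scaler, medians, report


def _transform_preprocess(table, intervals, encoding, scaler, medians):
    """Apply a fitted chain to new rows (median fill; never refits)."""
    table, _ = trim_to_interval(table, intervals)
    frame = table.frame.copy()
    for col in table.continuous_columns:
        frame[col] = frame[col].fillna(medians[col])
    table = CohortTable(frame, table.schema, table.family)
    table = impute_boolean(table)
    table, _ = encode_ordinal(table, encoding)
    table, _ = zscore(table, state=scaler)
    return table


def _feature_blocks(table: CohortTable, encoding: OrdinalEncoding):
    cont = table.continuous_columns
    toks = table.boolean_columns + table.categorical_columns
    x_num = table.frame[cont].to_numpy(dtype=float) if cont else None
    x_cat = table.frame[toks].to_numpy(dtype=int) if toks else None
    cards = [2 if c in table.boolean_columns else encoding.cardinality(c) for c in toks]
    return x_num, x_cat, cards, cont, toks


def fit_family(
    table: CohortTable,
    config: PipelineConfig,
    split_seed: int,
    boost_seed: int,
    attn_seed: int,
) -> FamilyArtifacts:
    """Split, preprocess, run the SHAP feature-weight loop on the boosting
    head, then train the attention head on (optionally) weighted features."""
    split = split_train_val_test(table, ratios=config.split_ratios, seed=split_seed)
    train, intervals, encoding, scaler, medians, report = _fit_preprocess(
        split.train, seed=boost_seed
    )
    val = _transform_preprocess(split.val, intervals, encoding, scaler, medians)
    test = _transform_preprocess(split.test, intervals, encoding, scaler, medians)

    # ---- boosting stage with per-epoch SHAP reweighting ----
    feature_names = train.feature_names
    x_train = train.features().to_numpy(dtype=float)
    x_val = val.features().to_numpy(dtype=float)
    y_train, y_val = train.labels, val.labels
    state = FeatureWeightState(feature_names=tuple(feature_names), damping=config.weight_damping)
    model = None
    for _ in range(config.weight_epochs):
        xw = apply_weights(x_train, state)
        model = fit_boosting(
            xw, y_train,
            params=None, focal=config.focal,
            num_boost_round=config.boost_rounds, seed=boost_seed,
            feature_names=feature_names,
        )
        contrib = shap_contributions(model, xw)
        state = update_feature_weights(state, contrib)
    xw_train = apply_weights(x_train, state)
    model = fit_boosting(
        xw_train, y_train, params=None, focal=config.focal,
        num_boost_round=config.boost_rounds, seed=boost_seed,
        feature_names=feature_names,
    )

    # ---- attention stage ----
    x_num_tr, x_cat_tr, cards, cont, toks = _feature_blocks(train, encoding)
    x_num_va, x_cat_va, _, _, _ = _feature_blocks(val, encoding)
    x_num_te, x_cat_te, _, _, _ = _feature_blocks(test, encoding)
    if config.weights_feed_attention and x_num_tr is not None:
        cont_w = np.array([state.weights[feature_names.index(c)] for c in cont])
        x_num_tr = x_num_tr * cont_w
        x_num_va = x_num_va * cont_w
        x_num_te = x_num_te * cont_w
    attn = AttentionClassifier(
        n_numeric=len(cont), cat_cardinalities=cards,
        config=config.architecture, seed=attn_seed,
    )
    rule = DecisionRule(tau=config.tau)
    train_model(
        attn,
        x_num_tr, x_cat_tr, y_train,
        x_num_va, x_cat_va, y_val,
        thresholds=config.thresholds, rule=rule,
        lr=config.attention_lr, batch_size=config.attention_batch, seed=attn_seed,
    )

    # ---- evaluation on the held-out test rows ----
    test_probs = attn.predict_proba(x_num_te, x_cat_te)[:, 1]
    report_test = evaluate_scores(test.labels, test_probs, rule=rule)
    sweep = threshold_sweep(test.labels, test_probs)
    return FamilyArtifacts(
        family=table.family,
        split=split,
        intervals=intervals,
        encoding=encoding,
        scaler=scaler,
        train_medians=medians,
        weight_state=state,
        boost_model=model,
        attention_model=attn,
        report=report,
        metrics_test=report_test.as_dict(),
        sweep=sweep,
    )


# --------------------------------------------------------------------------
# pipeline entry points
# --------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig | None = None) -> PipelineArtifacts:
    config = config if config is not None else PipelineConfig()
    seed = config.seed
    physio_raw, factor_raw = assemble_datasets(
        config.augmentation, seed=stage_seed(seed, "augment")
    )
    miss_seed = stage_seed(seed, "missingness")
    physio_raw = inject_missingness(
        physio_raw, config.missing_continuous_rate, config.missing_categorical_rate, miss_seed
    )
    factor_raw = inject_missingness(
        factor_raw, config.missing_continuous_rate, config.missing_categorical_rate, miss_seed + 1
    )

    physio = fit_family(
        physio_raw, config,
        split_seed=stage_seed(seed, "split_physio"),
        boost_seed=stage_seed(seed, "boost_physio"),
        attn_seed=stage_seed(seed, "attention_physio"),
    )
    factor = fit_family(
        factor_raw, config,
        split_seed=stage_seed(seed, "split_factor"),
        boost_seed=stage_seed(seed, "boost_factor"),
        attn_seed=stage_seed(seed, "attention_factor"),
    )

    # fuse the two heads over index-paired test rows
    n = min(physio.split.test.n_rows, factor.split.test.n_rows)
    p1 = _head_probs(physio, config)[:n]
    p2 = _head_probs(factor, config)[:n]
    _, audit = fuse_batch(p1, p2, rule=DecisionRule(tau=config.tau))

    manifest = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "master_seed": seed,
        "stage_seeds": {k: stage_seed(seed, k) for k in STAGE_IDS},
        "rows": {
            "physiological": physio_raw.n_rows,
            "pathogenic": factor_raw.n_rows,
        },
        "metrics": {
            "physiological": physio.metrics_test,
            "pathogenic": factor.metrics_test,
        },
    }
    artifacts = PipelineArtifacts(
        config=config, physio=physio, factor=factor, fused_audit=audit, manifest=manifest
    )
    _write_artifacts(artifacts)
    return artifacts


def _head_probs(fam: FamilyArtifacts, config: PipelineConfig) -> np.ndarray:
    # recompute the attention head's test probabilities from stored state
    test = _transform_preprocess(
        fam.split.test, fam.intervals, fam.encoding, fam.scaler, fam.train_medians
    )
    x_num, x_cat, _, cont, _ = _feature_blocks(test, fam.encoding)
    if config.weights_feed_attention and x_num is not None:
        names = list(fam.weight_state.feature_names)
        cont_w = np.array([fam.weight_state.weights[names.index(c)] for c in cont])
        x_num = x_num * cont_w
    return fam.attention_model.predict_proba(x_num, x_cat)[:, 1]


def _write_artifacts(artifacts: PipelineArtifacts) -> None:
    out = Path(artifacts.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(json.dumps(artifacts.manifest, indent=2))
    artifacts.fused_audit.to_csv(out / "fused_predictions.csv", index=False)
    for fam in (artifacts.physio, artifacts.factor):
        prefix = out / fam.family
        prefix.mkdir(exist_ok=True)
        (prefix / "metrics_test.json").write_text(json.dumps(fam.metrics_test, indent=2))
        fam.sweep.to_csv(prefix / "threshold_sweep.csv", index=False)
        (prefix / "preprocess_report.json").write_text(json.dumps(fam.report.as_dict(), indent=2))
        (prefix / "feature_weights.json").write_text(
            json.dumps(
                {
                    "features": list(fam.weight_state.feature_names),
                    "weights": fam.weight_state.weights.tolist(),
                    "epoch": fam.weight_state.epoch,
                },
                indent=2,
            )
        )
        (prefix / "scaler.json").write_text(json.dumps(fam.scaler.as_dict(), indent=2))
        (prefix / "encoding.json").write_text(json.dumps(fam.encoding.maps, indent=2))
        fam.boost_model.save(prefix / "boost_model.txt")
        fam.attention_model.save(prefix / "attention_model.npz")


def predict(
    artifacts: PipelineArtifacts,
    physio_table: CohortTable,
    factor_table: CohortTable,
) -> pd.DataFrame:
    """Batch prediction with fitted artifacts (never refits).

    Both tables must follow the training schemas; rows are paired by index.
    Returns the fused audit table.
    """
    config = artifacts.config
    probs = []
    for fam, table in ((artifacts.physio, physio_table), (artifacts.factor, factor_table)):
        expected = [s.name for s in fam.split.train.schema]
        got = table.feature_names
        if got != expected:
            raise ValueError(
                f"schema drift for {fam.family}: expected columns {expected}, got {got}"
            )
        if table.n_rows == 0:
            probs.append(np.zeros(0))
            continue
        transformed = _transform_preprocess(
            table, fam.intervals, fam.encoding, fam.scaler, fam.train_medians
        )
        x_num, x_cat, _, cont, _ = _feature_blocks(transformed, fam.encoding)
        if config.weights_feed_attention and x_num is not None:
            names = list(fam.weight_state.feature_names)
            cont_w = np.array([fam.weight_state.weights[names.index(c)] for c in cont])
            x_num = x_num * cont_w
        probs.append(fam.attention_model.predict_proba(x_num, x_cat)[:, 1])
    n = min(len(probs[0]), len(probs[1]))
    if n == 0:
        return pd.DataFrame(
            columns=["physio_prob", "factor_prob", "physio_decision", "factor_decision", "risk_level"]
        )
    _, audit = fuse_batch(probs[0][:n], probs[1][:n], rule=DecisionRule(tau=config.tau))
    return audit


def demo_config(out_dir: str = "artifacts", seed: int = 0) -> PipelineConfig:
    """A desk-scale configuration that completes in minutes on one CPU."""
    return PipelineConfig(
        seed=seed,
        out_dir=out_dir,
        augmentation=AugmentationConfig(
            target_negatives=600, target_positives=500,
            source_positives_physio=120, source_positives_pathogenic=110,
        ),
        boost_rounds=40,
        weight_epochs=2,
        architecture=ArchitectureConfig(embed_dim=16, n_heads=4, n_self_blocks=2),
        thresholds=StoppingThresholds(max_epochs=8),
        attention_batch=128,
    )
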