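"""Synthetic cohort generation, class rebalancing and data splits.

Two feature families are emulated:

* *physiological indicators* — continuous vitals/lab values.  Negatives are
  drawn uniformly inside clinical reference intervals ("healthy by
  definition"); positives come from per-indicator truncated normals whose
  means are displaced from the reference midpoint by a configurable effect
  size, so a fraction of rows carries at least one out-of-range value.
* *pathogenic factors* — Boolean/categorical risk flags plus age, glucose
  and BMI, mirroring public stroke-registry tables.  Positives carry
  elevated Bernoulli rates and shifted continuous covariates.

The minority (positive) class starts at registry-scale counts (836
physiological / 783 pathogenic source rows) and is oversampled to the
target count with a fuzzy-c-means-guided SMOTE: the minority class is
soft-clustered, neighbour pairs are drawn within the same hard-assigned
cluster, and synthetic rows interpolate between the pair.  Defaults yield
6,000 negatives and 5,000 positives per family (imbalance rate 120%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .schema import (
    DEFAULT_REFERENCE_RANGES,
    LABEL_COLUMN,
    PATHOGENIC_SCHEMA,
    PHYSIOLOGICAL_SCHEMA,
    CohortTable,
    ReferenceRangeTable,
    SchemaError,
)


class ConfigError(ValueError):
    """Raised for invalid generator / augmentation configuration."""


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

#: default mean displacement of positive-class indicators, in units of the
#: negative-class (uniform within range) standard deviation.
DEFAULT_SHIFTS: dict[str, float] = {
    "blood_glucose": 1.5,
    "systolic_bp": 1.5,
    "diastolic_bp": 1.5,
    "cholesterol": 1.5,
    "ldl": 1.5,
    "triglycerides": 1.5,
    "hdl": -1.0,
    "blood_oxygen": -1.0,
}


@dataclass(frozen=True)
class ShiftProfile:
    """Positive-class displacement, in pooled-SD units, per indicator.

    ``out_of_range_fraction`` is the minimum fraction of positive rows forced
    to carry at least one out-of-range indicator value (the natural rate under
    the default shifts is already higher).
    """

    shifts: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SHIFTS))
    out_of_range_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.out_of_range_fraction < 0:
            raise ConfigError("out_of_range_fraction must be >= 0")
        for name, s in self.shifts.items():
            if not np.isfinite(s):
                raise ConfigError(f"non-finite shift for {name!r}")

    @classmethod
    def null(cls) -> "ShiftProfile":
        return cls(shifts={}, out_of_range_fraction=0.0)


@dataclass(frozen=True)
class AugmentationConfig:
    """Targets and knobs for cohort assembly and SMOTE rebalancing."""

    target_negatives: int = 6000
    target_positives: int = 5000
    source_positives_physio: int = 836
    source_positives_pathogenic: int = 783
    smote_k: int = 5
    n_clusters: int = 3
    fuzzifier: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_negatives < 1 or self.target_positives < 1:
            raise ConfigError("target counts must be >= 1")
        if self.fuzzifier <= 1:
            raise ConfigError("fuzzifier must be > 1")
        if self.smote_k < 1:
            raise ConfigError("smote_k must be >= 1")

    @property
    def imbalance_rate(self) -> float:
        """Negatives per 100 positives (percent)."""
        return 100.0 * self.target_negatives / self.target_positives


@dataclass
class DataSplit:
    """Disjoint stratified train / validation / test partition."""

    train: CohortTable
    val: CohortTable
    test: CohortTable
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray


# --------------------------------------------------------------------------
# physiological generators
# --------------------------------------------------------------------------

def _check_ranges(ranges: ReferenceRangeTable) -> None:
    required = [s.name for s in PHYSIOLOGICAL_SCHEMA]
    missing = [n for n in required if n not in ranges]
    if missing:
        raise SchemaError(f"reference ranges missing indicators: {missing}")


def generate_negative_samples(
    ranges: ReferenceRangeTable = DEFAULT_REFERENCE_RANGES,
    n: int = 6000,
    seed: int = 0,
) -> CohortTable:
    """Negative (no-risk) physiological rows, uniform within each interval."""
    _check_ranges(ranges)
    if n < 0:
        raise ConfigError("n must be >= 0")
    rng = np.random.default_rng(seed)
    data = {
        name: rng.uniform(ranges.low(name), ranges.high(name), size=n)
        for name in [s.name for s in PHYSIOLOGICAL_SCHEMA]
    }
    data[LABEL_COLUMN] = np.zeros(n, dtype=int)
    return CohortTable(pd.DataFrame(data), PHYSIOLOGICAL_SCHEMA, "physiological")


def generate_positive_samples(
    ranges: ReferenceRangeTable = DEFAULT_REFERENCE_RANGES,
    n: int = 836,
    shift_profile: ShiftProfile | None = None,
    seed: int = 0,
) -> CohortTable:
    """Positive (at-risk) physiological rows with displaced distributions.

    Each indicator is a normal truncated to the plausibility interval (3x the
    reference width, same centre) with mean ``midpoint + shift * sd`` where
    ``sd`` is the uniform-within-range SD ``width / sqrt(12)``.
    """
    _check_ranges(ranges)
    if n < 0:
        raise ConfigError("n must be >= 0")
    profile = shift_profile if shift_profile is not None else ShiftProfile()
    rng = np.random.default_rng(seed)
    names = [s.name for s in PHYSIOLOGICAL_SCHEMA]
    data: dict[str, np.ndarray] = {}
    for name in names:
        sd = ranges.width(name) / np.sqrt(12.0)
        mean = ranges.midpoint(name) + profile.shifts.get(name, 0.0) * sd
        lo, hi = ranges.plausibility(name)
        a, b = (lo - mean) / sd, (hi - mean) / sd
        data[name] = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
    frame = pd.DataFrame(data)

    # enforce the configured minimum out-of-range fraction on shifted columns
    shifted = [c for c, s in profile.shifts.items() if s != 0.0 and c in frame.columns]
    if n > 0 and shifted and profile.out_of_range_fraction > 0:
        need = int(np.ceil(profile.out_of_range_fraction * n))
        in_range = np.ones(n, dtype=bool)
        for name in names:
            lo, hi = ranges[name]
            in_range &= (frame[name].to_numpy() >= lo) & (frame[name].to_numpy() <= hi)
        already_out = int((~in_range).sum())
        if already_out < need:
            candidates = np.flatnonzero(in_range)
            pick = rng.choice(candidates, size=need - already_out, replace=False)
            for i in pick:
                name = shifted[rng.integers(len(shifted))]
                lo, hi = ranges[name]
                margin = 0.05 * ranges.width(name)
                if profile.shifts[name] > 0:
                    frame.iloc[i, frame.columns.get_loc(name)] = hi + rng.uniform(0, margin) + 1e-9
                else:
                    frame.iloc[i, frame.columns.get_loc(name)] = lo - rng.uniform(0, margin) - 1e-9

    frame[LABEL_COLUMN] = np.ones(n, dtype=int)
    return CohortTable(frame, PHYSIOLOGICAL_SCHEMA, "physiological")


# --------------------------------------------------------------------------
# pathogenic generators
# --------------------------------------------------------------------------

#: Bernoulli rates for Boolean flags and frequency tables for categoricals,
#: separately for negatives and positives (positives carry elevated risk
#: factor prevalence and older / more dysglycaemic continuous covariates).
PATHOGENIC_PARAMS: dict[str, dict] = {
    "negative": {
        "hypertension": 0.08,
        "heart_disease": 0.04,
        "gender": {"Female": 0.58, "Male": 0.41, "Other": 0.01},
        "ever_married": {"No": 0.36, "Yes": 0.64},
        "work_type": {
            "Govt_job": 0.13,
            "Never_worked": 0.02,
            "Private": 0.57,
            "Self-employed": 0.15,
            "children": 0.13,
        },
        "residence_type": {"Rural": 0.49, "Urban": 0.51},
        "smoking_status": {
            "formerly smoked": 0.17,
            "never smoked": 0.52,
            "smokes": 0.15,
            "Unknown": 0.16,
        },
        "age": (42.0, 18.0),  # mean, sd; clipped to [1, 95]
        "avg_glucose_level": (100.0, 30.0),  # mg/dL, clipped to [50, 300]
        "bmi": (28.0, 6.5),  # clipped to [12, 60]
    },
    "positive": {
        "hypertension": 0.27,
        "heart_disease": 0.19,
        "gender": {"Female": 0.55, "Male": 0.44, "Other": 0.01},
        "ever_married": {"No": 0.12, "Yes": 0.88},
        "work_type": {
            "Govt_job": 0.15,
            "Never_worked": 0.01,
            "Private": 0.58,
            "Self-employed": 0.24,
            "children": 0.02,
        },
        "residence_type": {"Rural": 0.46, "Urban": 0.54},
        "smoking_status": {
            "formerly smoked": 0.27,
            "never smoked": 0.45,
            "smokes": 0.18,
            "Unknown": 0.10,
        },
        "age": (68.0, 12.0),
        "avg_glucose_level": (130.0, 55.0),
        "bmi": (30.0, 6.0),
    },
}

_PATHO_CLIPS = {"age": (1.0, 95.0), "avg_glucose_level": (50.0, 300.0), "bmi": (12.0, 60.0)}


def generate_pathogenic_samples(
    n: int,
    label: int,
    params: dict | None = None,
    seed: int = 0,
) -> CohortTable:
    """Pathogenic-factor rows for one class (``label`` 0 or 1)."""
    if n < 0:
        raise ConfigError("n must be >= 0")
    if label not in (0, 1):
        raise ConfigError("label must be 0 or 1")
    p = params if params is not None else PATHOGENIC_PARAMS["positive" if label else "negative"]
    rng = np.random.default_rng(seed)
    data: dict[str, np.ndarray] = {}
    for spec in PATHOGENIC_SCHEMA:
        conf = p[spec.name]
        if spec.kind == "continuous":
            mean, sd = conf
            lo, hi = _PATHO_CLIPS[spec.name]
            data[spec.name] = np.clip(rng.normal(mean, sd, size=n), lo, hi)
        elif spec.kind == "boolean":
            data[spec.name] = rng.binomial(1, conf, size=n).astype(int)
        else:
            cats = sorted(conf)
            probs = np.array([conf[c] for c in cats], dtype=float)
            probs = probs / probs.sum()
            data[spec.name] = rng.choice(cats, size=n, p=probs)
    frame = pd.DataFrame(data)
    frame[LABEL_COLUMN] = np.full(n, label, dtype=int)
    return CohortTable(frame, PATHOGENIC_SCHEMA, "pathogenic")


# --------------------------------------------------------------------------
# fuzzy-c-means guided SMOTE
# --------------------------------------------------------------------------

def fuzzy_c_means(
    x: np.ndarray,
    n_clusters: int,
    fuzzifier: float = 2.0,
    rng: np.random.Generator | None = None,
    max_iter: int = 100,
    tol: float = 1e-5,
) -> tuple[np.ndarray, np.ndarray]:
    """Plain fuzzy c-means.  Returns (memberships (n, c), centres (c, d))."""
    rng = rng if rng is not None else np.random.default_rng(0)
    n = x.shape[0]
    c = min(n_clusters, n)
    u = rng.dirichlet(np.ones(c), size=n)
    m = fuzzifier
    centres = np.zeros((c, x.shape[1]))
    for _ in range(max_iter):
        um = u ** m
        centres = (um.T @ x) / np.maximum(um.sum(axis=0)[:, None], 1e-12)
        d = np.linalg.norm(x[:, None, :] - centres[None, :, :], axis=2)
        d = np.maximum(d, 1e-12)
        inv = d ** (-2.0 / (m - 1.0))
        new_u = inv / inv.sum(axis=1, keepdims=True)
        if np.max(np.abs(new_u - u)) < tol:
            u = new_u
            break
        u = new_u
    return u, centres


def smote_balance(
    minority: CohortTable,
    target: int,
    config: AugmentationConfig | None = None,
    seed: int | None = None,
) -> CohortTable:
    """Oversample a minority-class table to exactly ``target`` rows.

    Original rows are preserved verbatim.  Each synthetic row interpolates
    between a minority row and one of its ``smote_k`` nearest neighbours from
    the same hard-assigned fuzzy cluster: continuous coordinates take
    ``x_i + u * (x_j - x_i)`` with ``u ~ Uniform(0, 1)``; Boolean/categorical
    coordinates take the nearer parent's value (``u < 0.5`` keeps parent i).
    """
    config = config if config is not None else AugmentationConfig()
    n0 = minority.n_rows
    if target < n0:
        raise ConfigError(f"target {target} < current minority count {n0}")
    if target == n0:
        return minority.copy()
    if n0 < 2:
        raise ConfigError("minority must have >= 2 rows for interpolation")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    cont = minority.continuous_columns
    other = [c for c in minority.feature_names if c not in cont]
    x = minority.frame[cont].to_numpy(dtype=float)
    mu, sd = x.mean(axis=0), x.std(axis=0)
    degenerate = bool(np.all(sd < 1e-12)) and all(
        minority.frame[c].nunique() <= 1 for c in other
    )
    if degenerate:
        warnings.warn("degenerate all-identical minority: duplicating rows")
        reps = minority.frame.iloc[rng.integers(0, n0, size=target - n0)]
        frame = pd.concat([minority.frame, reps], ignore_index=True)
        return CohortTable(frame, minority.schema, minority.family)

    z = (x - mu) / np.where(sd < 1e-12, 1.0, sd)
    u_mem, _ = fuzzy_c_means(z, config.n_clusters, config.fuzzifier, rng)
    hard = u_mem.argmax(axis=1)

    # nearest neighbours within the same hard cluster
    k = min(config.smote_k, n0 - 1)
    neighbours: list[np.ndarray] = []
    for i in range(n0):
        same = np.flatnonzero(hard == hard[i])
        same = same[same != i]
        if same.size == 0:  # singleton cluster: fall back to global neighbours
            same = np.flatnonzero(np.arange(n0) != i)
        d = np.linalg.norm(z[same] - z[i], axis=1)
        order = same[np.argsort(d, kind="stable")]
        neighbours.append(order[:k])

    n_new = target - n0
    base = rng.integers(0, n0, size=n_new)
    rows = []
    label = int(minority.frame[LABEL_COLUMN].iloc[0])
    for i in base:
        nbrs = neighbours[i]
        j = int(nbrs[rng.integers(len(nbrs))])
        u = rng.uniform()
        row = {}
        for c_idx, cname in enumerate(cont):
            xi, xj = x[i, c_idx], x[j, c_idx]
            row[cname] = xi + u * (xj - xi)
        for cname in other:
            src = i if u < 0.5 else j
            row[cname] = minority.frame[cname].iloc[src]
        row[LABEL_COLUMN] = label
        rows.append(row)
    frame = pd.concat([minority.frame, pd.DataFrame(rows)], ignore_index=True)
    return CohortTable(frame, minority.schema, minority.family)


# --------------------------------------------------------------------------
# cohort assembly and splits
# --------------------------------------------------------------------------

def assemble_datasets(
    config: AugmentationConfig | None = None,
    seed: int = 0,
    ranges: ReferenceRangeTable = DEFAULT_REFERENCE_RANGES,
) -> tuple[CohortTable, CohortTable]:
    """Build the two balanced study tables (physiological, pathogenic).

    Each table ends with ``target_negatives`` negatives and
    ``target_positives`` positives; positives are a SMOTE expansion of the
    registry-scale source counts.  Rows are shuffled deterministically.
    """
    config = config if config is not None else AugmentationConfig()
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]

    # source counts never exceed the target (down-scaled runs)
    n_src_phys = min(config.source_positives_physio, config.target_positives)
    n_src_path = min(config.source_positives_pathogenic, config.target_positives)

    phys_neg = generate_negative_samples(ranges, config.target_negatives, seeds[0])
    phys_src = generate_positive_samples(ranges, n_src_phys, seed=seeds[1])
    phys_pos = smote_balance(phys_src, config.target_positives, config, seed=seeds[2])

    path_neg = generate_pathogenic_samples(config.target_negatives, 0, seed=seeds[3])
    path_src = generate_pathogenic_samples(n_src_path, 1, seed=seeds[4])
    path_pos = smote_balance(path_src, config.target_positives, config, seed=seeds[5])

    def _merge(neg: CohortTable, pos: CohortTable, shuffle_seed: int) -> CohortTable:
        frame = pd.concat([neg.frame, pos.frame], ignore_index=True)
        perm = np.random.default_rng(shuffle_seed).permutation(len(frame))
        return CohortTable(frame.iloc[perm].reset_index(drop=True), neg.schema, neg.family)

    return _merge(phys_neg, phys_pos, seeds[0] ^ 1), _merge(path_neg, path_pos, seeds[3] ^ 1)


def _largest_remainder(total: int, ratios: np.ndarray) -> np.ndarray:
    ratios = np.asarray(ratios, dtype=float)
    if ratios.sum() <= 0 or (ratios < 0).any():
        raise ConfigError("ratios must be positive with nonzero sum")
    quota = total * ratios / ratios.sum()
    base = np.floor(quota).astype(int)
    rem = quota - base
    extra = total - base.sum()
    order = np.argsort(-rem, kind="stable")
    base[order[:extra]] += 1
    return base


def _stratified_allocation(class_sizes: list[int], ratios: np.ndarray) -> np.ndarray:
    """Per-class largest-remainder allocation, corrected so the part totals
    equal the global largest-remainder sizes (each part within 1 of
    proportional).  Correction moves one row at a time; tie-break by class
    label order then part index."""
    total = int(sum(class_sizes))
    target = _largest_remainder(total, ratios)
    alloc = np.stack([_largest_remainder(nc, ratios) for nc in class_sizes])
    diff = alloc.sum(axis=0) - target
    while diff.any():
        p_over = int(np.flatnonzero(diff > 0)[0])
        p_under = int(np.flatnonzero(diff < 0)[0])
        for c in range(len(class_sizes)):
            if alloc[c, p_over] > 0:
                alloc[c, p_over] -= 1
                alloc[c, p_under] += 1
                break
        diff = alloc.sum(axis=0) - target
    return alloc


def split_train_val_test(
    table: CohortTable,
    ratios: tuple[float, float, float] = (7, 2, 1),
    seed: int = 0,
) -> DataSplit:
    """Label-stratified 3-way partition with largest-remainder rounding."""
    if table.n_rows == 0:
        raise ConfigError("cannot split an empty table")
    ratios_arr = np.asarray(ratios, dtype=float)
    labels = table.labels
    classes = sorted(np.unique(labels))
    class_rows = [np.flatnonzero(labels == c) for c in classes]
    alloc = _stratified_allocation([len(r) for r in class_rows], ratios_arr)
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[], [], []]
    for rows, counts in zip(class_rows, alloc):
        perm = rng.permutation(rows)
        start = 0
        for p, cnt in enumerate(counts):
            parts[p].extend(perm[start : start + cnt].tolist())
            start += cnt
    idxs = [np.sort(np.asarray(p, dtype=int)) for p in parts]
    return DataSplit(
        train=table.subset(idxs[0]),
        val=table.subset(idxs[1]),
        test=table.subset(idxs[2]),
        train_idx=idxs[0],
        val_idx=idxs[1],
        test_idx=idxs[2],
    )


def stratified_cv_splits(
    table: CohortTable,
    k: int = 5,
    holdout_fraction: float = 0.2,
    train_val_ratio: tuple[float, float] = (9, 1),
    seed: int = 0,
) -> list[DataSplit]:
    """k stratified folds; per fold the held-out fold (1/k of rows) is the
    test set and the remainder is split ``train_val_ratio`` into
    train/validation, stratified by label throughout."""
    from sklearn.model_selection import StratifiedKFold

    if k < 2:
        raise ConfigError("k must be >= 2")
    labels = table.labels
    _, counts = np.unique(labels, return_counts=True)
    if (counts < k).any():
        raise ConfigError("each class needs >= k members for stratification")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    splits: list[DataSplit] = []
    for fold, (rest_idx, hold_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        rest = table.subset(rest_idx)
        ratios3 = (train_val_ratio[0], train_val_ratio[1], 0)
        inner = split_train_val_test(rest, ratios=ratios3, seed=seed + 1 + fold)
        splits.append(
            DataSplit(
                train=inner.train,
                val=inner.val,
                test=table.subset(hold_idx),
                train_idx=rest_idx[inner.train_idx],
                val_idx=rest_idx[inner.val_idx],
                test_idx=np.asarray(hold_idx, dtype=int),
            )
        )
    return splits


def inject_missingness(
    table: CohortTable,
    continuous_rate: float = 0.03,
    categorical_rate: float = 0.02,
    seed: int = 0,
) -> CohortTable:
    """Blank a random fraction of entries (MCAR) to exercise imputation."""
    rng = np.random.default_rng(seed)
    frame = table.frame.copy()
    for col in table.continuous_columns:
        mask = rng.uniform(size=len(frame)) < continuous_rate
        frame.loc[mask, col] = np.nan
    for col in table.boolean_columns + table.categorical_columns:
        mask = rng.uniform(size=len(frame)) < categorical_rate
        frame.loc[mask, col] = np.nan
    return CohortTable(frame, table.schema, table.family)
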