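"""Preprocessing chain: interval trimming, chained-equation imputation,
Boolean/categorical handling, ordinal encoding and z-score scaling.

Order of operations for a cohort table:

1. *Interval trimming* — continuous values outside a plausibility interval
   (default 3x the reference width, same centre) are marked missing, as are
   zero-filled continuous entries (zero is an instrument placeholder for
   the vitals/lab panels modelled here).
2. *MICE* — ridge-regularised chained-equation imputation over the
   continuous block (10 iterations, seeded), clipped to the plausibility
   interval.  An all-missing column falls back to the label-stratified
   median with a warning.
3. *Boolean/categorical* — a missing Boolean flag defaults to 0 where zero
   means "factor absent"; missing categoricals become an explicit
   ``Unknown`` category.
4. *Ordinal encoding* — categories to consecutive integers, lexicographic;
   unseen categories at transform time map to a dedicated Unknown code.
5. *Z-score* — continuous columns standardised with statistics fitted on
   training rows only; zero-variance columns map to all-zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import UNKNOWN, CohortTable, ReferenceRangeTable


@dataclass
class PreprocessReport:
    """Append-only log of what each step did to which column."""

    missing_before: dict[str, float] = field(default_factory=dict)
    missing_after: dict[str, float] = field(default_factory=dict)
    trimmed_counts: dict[str, int] = field(default_factory=dict)
    imputation_method: dict[str, str] = field(default_factory=dict)
    encoding_maps: dict[str, dict] = field(default_factory=dict)

    @property
    def total_trimmed(self) -> int:
        return sum(self.trimmed_counts.values())

    def as_dict(self) -> dict:
        return {
            "missing_before": self.missing_before,
            "missing_after": self.missing_after,
            "trimmed_counts": self.trimmed_counts,
            "imputation_method": self.imputation_method,
            "encoding_maps": self.encoding_maps,
        }


def plausibility_intervals(
    table: CohortTable,
    ranges: ReferenceRangeTable | None = None,
    factor: float = 3.0,
) -> dict[str, tuple[float, float]]:
    """Per-column plausibility bounds: 3x the reference width where a
    reference range exists, otherwise robust empirical bounds
    (median +- 5 x IQR)."""
    out: dict[str, tuple[float, float]] = {}
    for col in table.continuous_columns:
        if ranges is not None and col in ranges:
            out[col] = ranges.plausibility(col, factor)
        else:
            v = table.frame[col].dropna()
            if len(v) == 0:
                out[col] = (-np.inf, np.inf)
                continue
            med = float(v.median())
            iqr = float(v.quantile(0.75) - v.quantile(0.25)) or float(v.std() or 1.0)
            out[col] = (med - 5 * iqr, med + 5 * iqr)
    return out


def trim_to_interval(
    table: CohortTable,
    intervals: dict[str, tuple[float, float]],
    report: PreprocessReport | None = None,
) -> tuple[CohortTable, PreprocessReport]:
    """Mark implausible and zero-filled continuous values as missing."""
    report = report if report is not None else PreprocessReport()
    frame = table.frame.copy()
    for col in table.continuous_columns:
        vals = frame[col]
        report.missing_before.setdefault(col, float(vals.isna().mean()))
        lo, hi = intervals.get(col, (-np.inf, np.inf))
        bad = (~vals.isna()) & ((vals < lo) | (vals > hi) | (vals == 0.0))
        report.trimmed_counts[col] = int(bad.sum())
        frame.loc[bad, col] = np.nan
    return CohortTable(frame, table.schema, table.family), report


def impute_continuous(
    table: CohortTable,
    intervals: dict[str, tuple[float, float]] | None = None,
    predictors: list[str] | None = None,
    max_iter: int = 10,
    seed: int = 0,
    report: PreprocessReport | None = None,
) -> tuple[CohortTable, PreprocessReport]:
    """MICE over the continuous block (ridge chained equations), clipped to
    the plausibility interval.  All-missing columns fall back to the
    label-stratified median with a warning."""
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer
    from sklearn.linear_model import Ridge

    report = report if report is not None else PreprocessReport()
    frame = table.frame.copy()
    cont = table.continuous_columns
    cols = predictors if predictors is not None else cont
    cols = [c for c in cols if c in cont]
    if not cols:
        return CohortTable(frame, table.schema, table.family), report

    labels = table.labels
    # fallback first: columns with nothing observed cannot be regressed
    for col in cont:
        if frame[col].isna().all():
            warnings.warn(f"column {col!r} is all-missing: stratified median fallback")
            for lab in np.unique(labels):
                stratum = labels == lab
                observed = frame.loc[~frame[col].isna() & stratum, col]
                if len(observed):
                    fill = float(observed.median())
                else:
                    rest = frame[col].dropna()
                    fill = float(rest.median()) if len(rest) else 0.0
                frame.loc[stratum & frame[col].isna(), col] = fill
            report.imputation_method[col] = "stratified_median"

    block = frame[cont].to_numpy(dtype=float)
    if np.isnan(block).any():
        fully_observed = [c for c in cont if not frame[c].isna().any()]
        if not fully_observed and not any(~frame[c].isna().any() for c in cont):
            # MICE still works off partially observed columns via initial means
            pass
        imputer = IterativeImputer(
            estimator=Ridge(alpha=1.0, random_state=seed),
            max_iter=max_iter,
            random_state=seed,
            sample_posterior=False,
        )
        filled = imputer.fit_transform(block)
        if filled.shape[1] != len(cont):  # a column dropped as all-NaN (handled above)
            filled = block
        for j, col in enumerate(cont):
            if intervals and col in intervals:
                lo, hi = intervals[col]
                filled[:, j] = np.clip(filled[:, j], lo, hi)
            report.imputation_method.setdefault(col, "mice_ridge")
        frame[cont] = filled
    for col in cont:
        report.missing_after[col] = float(frame[col].isna().mean())
    return CohortTable(frame, table.schema, table.family), report


def impute_boolean(
    table: CohortTable,
    absent_means_zero: tuple[str, ...] | None = None,
) -> CohortTable:
    """Missing Booleans default to 0 where zero means "factor absent";
    missing categoricals become the explicit Unknown category."""
    frame = table.frame.copy()
    absent = set(absent_means_zero) if absent_means_zero is not None else set(table.boolean_columns)
    for col in table.boolean_columns:
        if col in absent:
            frame[col] = frame[col].fillna(0).astype(int)
        else:
            frame[col] = frame[col].astype(object).where(~frame[col].isna(), UNKNOWN)
    for col in table.categorical_columns:
        frame[col] = frame[col].astype(object).where(~frame[col].isna(), UNKNOWN)
    return CohortTable(frame, table.schema, table.family)


@dataclass
class OrdinalEncoding:
    """Per-column category -> code maps (lexicographic), with a dedicated
    Unknown code at ``len(categories)`` for unseen values."""

    maps: dict[str, dict] = field(default_factory=dict)

    def categories(self, col: str) -> list:
        return list(self.maps[col])

    def unknown_code(self, col: str) -> int:
        return len(self.maps[col])

    def cardinality(self, col: str) -> int:
        return len(self.maps[col])

    def transform_column(self, col: str, values: pd.Series) -> np.ndarray:
        mapping = self.maps[col]
        out = np.empty(len(values), dtype=int)
        unseen = 0
        for i, v in enumerate(values):
            if v in mapping:
                out[i] = mapping[v]
            else:
                out[i] = self.unknown_code(col)
                unseen += 1
        if unseen:
            warnings.warn(f"{unseen} unseen categories in {col!r} mapped to Unknown code")
        return out

    def inverse_column(self, col: str, codes: np.ndarray) -> list:
        rev = {v: k for k, v in self.maps[col].items()}
        return [rev.get(int(c), UNKNOWN) for c in codes]


def encode_ordinal(
    table: CohortTable,
    encoding: OrdinalEncoding | None = None,
    report: PreprocessReport | None = None,
) -> tuple[CohortTable, OrdinalEncoding]:
    """Encode categorical columns to consecutive integers (lexicographic).

    Pass a fitted ``encoding`` to transform new data; unseen categories map
    to the Unknown code with a warning."""
    frame = table.frame.copy()
    cats = table.categorical_columns
    if encoding is None:
        encoding = OrdinalEncoding()
        for col in cats:
            cat_values = sorted(str(v) for v in frame[col].dropna().unique())
            encoding.maps[col] = {v: i for i, v in enumerate(cat_values)}
    for col in cats:
        frame[col] = encoding.transform_column(col, frame[col].astype(str))
    if report is not None:
        report.encoding_maps.update(encoding.maps)
    return CohortTable(frame, table.schema, table.family), encoding


@dataclass
class ScalerState:
    """Training-set means/SDs for z-scoring; zero-variance columns map to 0."""

    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"means": self.means, "sds": self.sds}


def zscore(
    table: CohortTable,
    fit_rows: np.ndarray | None = None,
    state: ScalerState | None = None,
) -> tuple[CohortTable, ScalerState]:
    """Standardise continuous columns.  Statistics come from ``fit_rows``
    (or a previously fitted ``state``); held-out rows are transformed with
    the training statistics, never their own."""
    frame = table.frame.copy()
    cont = table.continuous_columns
    if state is None:
        if fit_rows is None:
            fit_rows = np.arange(table.n_rows)
        fit_rows = np.asarray(fit_rows, dtype=int)
        if len(fit_rows) == 0:
            raise ValueError("empty fit set for scaler")
        state = ScalerState()
        for col in cont:
            v = frame[col].to_numpy(dtype=float)[fit_rows]
            state.means[col] = float(np.mean(v))
            sd = float(np.std(v))
            state.sds[col] = sd if sd > 1e-12 else 0.0
    for col in cont:
        v = frame[col].to_numpy(dtype=float)
        sd = state.sds[col]
        frame[col] = np.zeros_like(v) if sd == 0.0 else (v - state.means[col]) / sd
    return CohortTable(frame, table.schema, table.family), state


def preprocess_chain(
    table: CohortTable,
    ranges: ReferenceRangeTable | None = None,
    fit_rows: np.ndarray | None = None,
    encoding: OrdinalEncoding | None = None,
    scaler: ScalerState | None = None,
    seed: int = 0,
) -> tuple[CohortTable, OrdinalEncoding, ScalerState, PreprocessReport]:
    """Full chain: trim -> MICE -> Boolean/categorical fill -> encode ->
    z-score.  Pass fitted ``encoding``/``scaler`` to transform new data."""
    report = PreprocessReport()
    intervals = plausibility_intervals(table, ranges)
    table, report = trim_to_interval(table, intervals, report)
    table, report = impute_continuous(table, intervals, seed=seed, report=report)
    table = impute_boolean(table)
    table, encoding = encode_ordinal(table, encoding, report)
    table, scaler = zscore(table, fit_rows=fit_rows, state=scaler)
    return table, encoding, scaler, report


def collapse_repeated_measures(frame: pd.DataFrame, subject_col: str) -> pd.DataFrame:
    """Per-subject median collapse for repeated measurements (numeric
    columns take the median, others the first observed value)."""
    num = frame.select_dtypes(include=[np.number]).columns.difference([subject_col])
    agg = {c: "median" if c in num else "first" for c in frame.columns if c != subject_col}
    return frame.groupby(subject_col, sort=False).agg(agg).reset_index()
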