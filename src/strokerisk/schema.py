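"""Core tabular containers shared by every pipeline stage.

A cohort is a pandas DataFrame of mixed continuous / Boolean / categorical
features plus a binary outcome column (``stroke``), tagged with a column
schema and a feature *family*: ``physiological`` (continuous vitals and lab
values) or ``pathogenic`` (risk-factor flags in the style of public stroke
registries).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

LABEL_COLUMN = "stroke"

#: marker used for "recorded as unknown" in Boolean/categorical columns
UNKNOWN = "Unknown"

KINDS = ("continuous", "boolean", "categorical")
FAMILIES = ("physiological", "pathogenic")


class SchemaError(ValueError):
    """Raised when a table does not match its declared column schema."""


@dataclass(frozen=True)
class ColumnSpec:
    """Declaration of a single feature column."""

    name: str
    kind: str  # continuous | boolean | categorical
    family: str  # physiological | pathogenic

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise SchemaError(f"unknown column kind {self.kind!r} for {self.name!r}")
        if self.family not in FAMILIES:
            raise SchemaError(f"unknown family {self.family!r} for {self.name!r}")


@dataclass
class CohortTable:
    """A feature matrix with binary labels and a typed column schema.

    ``frame`` holds the feature columns (in schema order) plus the label
    column.  Invariants checked on construction: labels are present for every
    row and take values in {0, 1}; Boolean columns contain only 0, 1 or the
    unknown marker / NaN.
    """

    frame: pd.DataFrame
    schema: tuple[ColumnSpec, ...]
    family: str

    def __post_init__(self) -> None:
        self.schema = tuple(self.schema)
        if self.family not in FAMILIES:
            raise SchemaError(f"unknown family {self.family!r}")
        missing = [c.name for c in self.schema if c.name not in self.frame.columns]
        if missing:
            raise SchemaError(f"schema columns absent from frame: {missing}")
        if LABEL_COLUMN not in self.frame.columns:
            raise SchemaError(f"label column {LABEL_COLUMN!r} missing")
        labels = self.frame[LABEL_COLUMN]
        if labels.isna().any():
            raise SchemaError("missing labels are not allowed")
        if not labels.isin([0, 1]).all():
            raise SchemaError("labels must be 0/1")
        for col in self.boolean_columns:
            vals = self.frame[col].dropna()
            ok = vals.isin([0, 1, UNKNOWN])
            if not ok.all():
                raise SchemaError(f"boolean column {col!r} contains non-0/1 values")
        # feature columns in schema order, label last
        ordered = [c.name for c in self.schema] + [LABEL_COLUMN]
        self.frame = self.frame.loc[:, ordered].reset_index(drop=True)

    # ------------------------------------------------------------------ views
    @property
    def labels(self) -> np.ndarray:
        return self.frame[LABEL_COLUMN].to_numpy(dtype=int)

    @property
    def feature_names(self) -> list[str]:
        return [c.name for c in self.schema]

    @property
    def continuous_columns(self) -> list[str]:
        return [c.name for c in self.schema if c.kind == "continuous"]

    @property
    def boolean_columns(self) -> list[str]:
        return [c.name for c in self.schema if c.kind == "boolean"]

    @property
    def categorical_columns(self) -> list[str]:
        return [c.name for c in self.schema if c.kind == "categorical"]

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    def features(self) -> pd.DataFrame:
        return self.frame[self.feature_names]

    def subset(self, index: Iterable[int]) -> "CohortTable":
        idx = np.asarray(list(index), dtype=int)
        return CohortTable(self.frame.iloc[idx].reset_index(drop=True), self.schema, self.family)

    def copy(self) -> "CohortTable":
        return CohortTable(self.frame.copy(), self.schema, self.family)

    # ----------------------------------------------------------------- i/o
    def to_csv(self, path: str | Path) -> None:
        """Write the table as CSV plus a sidecar ``<name>.schema.json``."""
        path = Path(path)
        self.frame.to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".schema.json")
        payload = {
            "family": self.family,
            "label": LABEL_COLUMN,
            "columns": [
                {"name": c.name, "kind": c.kind, "family": c.family} for c in self.schema
            ],
        }
        sidecar.write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path, schema_path: str | Path | None = None) -> "CohortTable":
        path = Path(path)
        if schema_path is None:
            schema_path = path.with_suffix(path.suffix + ".schema.json")
        payload = json.loads(Path(schema_path).read_text())
        schema = tuple(ColumnSpec(**c) for c in payload["columns"])
        frame = pd.read_csv(path)
        return cls(frame, schema, payload["family"])


@dataclass(frozen=True)
class ReferenceRangeTable:
    """Clinical reference intervals for the physiological indicators.

    Immutable once constructed; every indicator must satisfy ``low < high``.
    """

    ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        frozen = {}
        for name, (low, high) in dict(self.ranges).items():
            low, high = float(low), float(high)
            if not low < high:
                raise SchemaError(f"reference range for {name!r} must have low < high")
            frozen[name] = (low, high)
        object.__setattr__(self, "ranges", frozen)

    def __contains__(self, name: str) -> bool:
        return name in self.ranges

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.ranges[name]

    @property
    def indicators(self) -> list[str]:
        return list(self.ranges)

    def low(self, name: str) -> float:
        return self.ranges[name][0]

    def high(self, name: str) -> float:
        return self.ranges[name][1]

    def midpoint(self, name: str) -> float:
        low, high = self.ranges[name]
        return 0.5 * (low + high)

    def width(self, name: str) -> float:
        low, high = self.ranges[name]
        return high - low

    def plausibility(self, name: str, factor: float = 3.0) -> tuple[float, float]:
        """Plausibility interval: same centre, ``factor``x the width."""
        mid, w = self.midpoint(name), self.width(name)
        return mid - factor * w / 2.0, mid + factor * w / 2.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ReferenceRangeTable":
        import yaml

        data = yaml.safe_load(Path(path).read_text())
        return cls({k: (v["low"], v["high"]) for k, v in data.items()})


# Standard adult clinical reference intervals.  The blood-pressure indicator
# is recorded as separate systolic/diastolic columns.  All values are
# overridable by passing a custom ReferenceRangeTable.
DEFAULT_REFERENCE_RANGES = ReferenceRangeTable(
    {
        "body_temperature": (36.1, 37.2),  # degC
        "systolic_bp": (90.0, 120.0),  # mmHg
        "diastolic_bp": (60.0, 80.0),  # mmHg
        "heart_rate": (60.0, 100.0),  # bpm
        "blood_oxygen": (95.0, 100.0),  # SpO2 %
        "uric_acid": (155.0, 428.0),  # umol/L
        "cholesterol": (2.8, 5.2),  # total, mmol/L
        "blood_glucose": (3.9, 6.1),  # fasting, mmol/L
        "hdl": (1.0, 1.6),  # mmol/L
        "ldl": (1.3, 3.4),  # mmol/L
        "triglycerides": (0.4, 1.7),  # mmol/L
        "bmi": (18.5, 24.9),  # kg/m^2
    }
)

PHYSIOLOGICAL_SCHEMA = tuple(
    ColumnSpec(name, "continuous", "physiological")
    for name in DEFAULT_REFERENCE_RANGES.indicators
)

# Pathogenic-factor table mirrors the public stroke-registry layout:
# Boolean flags, demographic categoricals and three continuous covariates.
PATHOGENIC_SCHEMA = (
    ColumnSpec("age", "continuous", "pathogenic"),
    ColumnSpec("avg_glucose_level", "continuous", "pathogenic"),
    ColumnSpec("bmi", "continuous", "pathogenic"),
    ColumnSpec("hypertension", "boolean", "pathogenic"),
    ColumnSpec("heart_disease", "boolean", "pathogenic"),
    ColumnSpec("gender", "categorical", "pathogenic"),
    ColumnSpec("ever_married", "categorical", "pathogenic"),
    ColumnSpec("work_type", "categorical", "pathogenic"),
    ColumnSpec("residence_type", "categorical", "pathogenic"),
    ColumnSpec("smoking_status", "categorical", "pathogenic"),
)
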