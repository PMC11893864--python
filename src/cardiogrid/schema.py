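"""Feature schema and the in-memory tabular dataset container.

The bundled heart-disease schema describes 13 clinical predictors (5 numeric,
8 nominal integer-coded) and a binary target where 1 marks presence of
disease.  Schemas are declarative: they drive CSV validation, synthetic-data
generation and the grid-image layout, and are shipped as a versioned
human-editable YAML document.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources as _importlib_resources
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError, ValidationError

NUMERIC = "numeric"
NOMINAL = "nominal"


@dataclass(frozen=True)
class FeatureSpec:
    """One feature: a name, a kind, and a closed domain.

    Numeric features carry a closed interval ``(low, high)``; nominal features
    carry a finite set of integer codes.
    """

    name: str
    kind: str
    domain: tuple

    def __post_init__(self) -> None:
        if self.kind not in (NUMERIC, NOMINAL):
            raise SchemaError(f"unknown feature kind {self.kind!r} for {self.name!r}")
        if self.kind == NUMERIC:
            low, high = self.domain
            if not low < high:
                raise SchemaError(
                    f"numeric domain for {self.name!r} must satisfy low < high, "
                    f"got ({low}, {high})"
                )
            object.__setattr__(self, "domain", (float(low), float(high)))
        else:
            codes = tuple(sorted(int(c) for c in self.domain))
            if not codes:
                raise SchemaError(f"nominal domain for {self.name!r} is empty")
            object.__setattr__(self, "domain", codes)

    @property
    def is_numeric(self) -> bool:
        return self.kind == NUMERIC

    def contains(self, value: float) -> bool:
        """Whether a (non-missing) value lies inside the declared domain."""
        if np.isnan(value):
            return False
        if self.is_numeric:
            low, high = self.domain
            return low <= value <= high
        return float(value).is_integer() and int(value) in self.domain

    def to_dict(self) -> dict:
        if self.is_numeric:
            return {"name": self.name, "kind": self.kind,
                    "domain": {"low": self.domain[0], "high": self.domain[1]}}
        return {"name": self.name, "kind": self.kind, "codes": list(self.domain)}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSpec":
        if d["kind"] == NUMERIC:
            return cls(d["name"], NUMERIC, (d["domain"]["low"], d["domain"]["high"]))
        return cls(d["name"], NOMINAL, tuple(d["codes"]))


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered predictors plus a binary target."""

    predictors: tuple
    target: FeatureSpec
    version: str = "1"
    # nominal codes that are really missingness indicators (e.g. thal=0)
    missing_codes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "predictors", tuple(self.predictors))
        names = [p.name for p in self.predictors]
        if len(set(names)) != len(names):
            raise SchemaError("predictor names must be unique")
        if self.target.kind != NOMINAL or len(self.target.domain) != 2:
            raise SchemaError("target must be nominal with exactly two codes")

    @property
    def predictor_names(self) -> list:
        return [p.name for p in self.predictors]

    @property
    def n_predictors(self) -> int:
        return len(self.predictors)

    @property
    def numeric_names(self) -> list:
        return [p.name for p in self.predictors if p.is_numeric]

    @property
    def nominal_names(self) -> list:
        return [p.name for p in self.predictors if not p.is_numeric]

    def spec(self, name: str) -> FeatureSpec:
        for p in self.predictors:
            if p.name == name:
                return p
        if name == self.target.name:
            return self.target
        raise SchemaError(f"unknown feature {name!r}")

    def fingerprint(self) -> str:
        """Stable hash of names/kinds/domains; identifies compatible data."""
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "predictors": [p.to_dict() for p in self.predictors],
            "target": self.target.to_dict(),
            "missing_codes": {k: list(v) for k, v in self.missing_codes.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSchema":
        return cls(
            predictors=tuple(FeatureSpec.from_dict(p) for p in d["predictors"]),
            target=FeatureSpec.from_dict(d["target"]),
            version=str(d.get("version", "1")),
            missing_codes={k: tuple(v) for k, v in d.get("missing_codes", {}).items()},
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FeatureSchema":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ValidationReport:
    """Cells flagged out-of-domain plus missingness bookkeeping."""

    out_of_domain: list = field(default_factory=list)  # (row, column) pairs
    missing_cells: list = field(default_factory=list)  # (row, column) pairs
    missing_indicator_cells: list = field(default_factory=list)  # e.g. thal=0

    @property
    def ok(self) -> bool:
        return not self.out_of_domain


@dataclass
class TabularDataset:
    """An n x d predictor matrix in schema order, with optional binary labels."""

    frame: pd.DataFrame
    labels: Optional[np.ndarray]
    schema: FeatureSchema
    report: Optional[ValidationReport] = None

    def __post_init__(self) -> None:
        cols = list(self.frame.columns)
        if cols != self.schema.predictor_names:
            raise SchemaError("frame columns must equal schema predictors in order")
        if len(self.frame) < 1:
            raise ValidationError("dataset must contain at least one row")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(self.frame):
                raise ValidationError("labels length must match row count")

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def d(self) -> int:
        return self.schema.n_predictors

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def validate(self) -> ValidationReport:
        """Flag every cell outside its feature domain; record missing cells."""
        rep = ValidationReport()
        vals = self.values
        for j, spec in enumerate(self.schema.predictors):
            col = vals[:, j]
            nanmask = np.isnan(col)
            for i in np.flatnonzero(nanmask):
                rep.missing_cells.append((int(i), spec.name))
            ok = np.zeros(len(col), dtype=bool)
            ok[nanmask] = True  # missing handled separately, not out-of-domain
            idx = np.flatnonzero(~nanmask)
            for i in idx:
                if spec.contains(col[i]):
                    ok[i] = True
            for i in np.flatnonzero(~ok):
                rep.out_of_domain.append((int(i), spec.name))
            mcodes = self.schema.missing_codes.get(spec.name, ())
            if mcodes:
                for i in idx:
                    if col[i] in mcodes:
                        rep.missing_indicator_cells.append((int(i), spec.name))
        self.report = rep
        return rep

    def with_values(self, values: np.ndarray, labels=None) -> "TabularDataset":
        """New dataset with the same schema and replaced cell values."""
        frame = pd.DataFrame(values, columns=self.schema.predictor_names)
        return TabularDataset(frame, self.labels if labels is None else labels,
                              self.schema)

    def subset(self, rows: Iterable[int]) -> "TabularDataset":
        rows = np.asarray(list(rows), dtype=int)
        frame = self.frame.iloc[rows].reset_index(drop=True)
        labels = None if self.labels is None else self.labels[rows]
        return TabularDataset(frame, labels, self.schema)


def dataset_from_arrays(values: np.ndarray, labels, schema: FeatureSchema,
                        ) -> TabularDataset:
    frame = pd.DataFrame(np.asarray(values, dtype=float),
                         columns=schema.predictor_names)
    return TabularDataset(frame, labels, schema)


def heart_schema() -> FeatureSchema:
    """The bundled 13-predictor heart-disease schema."""
    path = _importlib_resources.files("cardiogrid.resources") / "heart_schema.yaml"
    with path.open() as fh:
        return FeatureSchema.from_dict(yaml.safe_load(fh))
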