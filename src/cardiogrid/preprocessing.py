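"""Min-max normalization, median/mode imputation, and Tukey outlier flagging.

Normalization rescales each feature to [0, 1] via
``x_new = (x - min(X)) / (max(X) - min(X))`` with extremes taken from the
fitting data; unseen out-of-range values are clipped and degenerate
(constant) features map to 0.  All parameters are fitted on training data
and applied frozen to anything else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict

import numpy as np

from .errors import SchemaError, ValidationError
from .schema import TabularDataset


@dataclass
class NormalizationParams:
    feature_names: list
    mins: np.ndarray
    maxs: np.ndarray
    clip: bool = True

    @property
    def degenerate(self) -> np.ndarray:
        return self.mins == self.maxs

    def to_dict(self) -> dict:
        return {
            name: {"min": float(mn), "max": float(mx), "degenerate": bool(mn == mx)}
            for name, mn, mx in zip(self.feature_names, self.mins, self.maxs)
        }


def fit_minmax(train: TabularDataset) -> NormalizationParams:
    """Column-wise extremes of the fitting data (missing cells ignored)."""
    if train.n < 1:
        raise ValidationError("cannot fit normalization on an empty dataset")
    vals = train.values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mins = np.nanmin(vals, axis=0)
        maxs = np.nanmax(vals, axis=0)
    if np.isnan(mins).any():
        bad = train.schema.predictor_names[int(np.flatnonzero(np.isnan(mins))[0])]
        raise ValidationError(f"feature {bad!r} is entirely missing")
    if (mins == maxs).any():
        names = [train.schema.predictor_names[j]
                 for j in np.flatnonzero(mins == maxs)]
        warnings.warn(f"degenerate (constant) feature(s): {', '.join(names)}")
    return NormalizationParams(list(train.schema.predictor_names), mins, maxs)


def apply_minmax(data, params: NormalizationParams) -> np.ndarray:
    """Scale to [0, 1]; fitted min -> 0, fitted max -> 1, constants -> 0."""
    if isinstance(data, TabularDataset):
        if data.schema.predictor_names != params.feature_names:
            raise SchemaError("normalization params were fitted on a different schema")
        vals = data.values
    else:
        vals = np.asarray(data, dtype=float)
        if vals.ndim == 1:
            vals = vals[None, :]
        if vals.shape[1] != len(params.feature_names):
            raise SchemaError("column count does not match fitted parameters")
    span = params.maxs - params.mins
    safe = np.where(span == 0, 1.0, span)
    scaled = (vals - params.mins) / safe
    scaled[:, params.degenerate] = 0.0
    if params.clip:
        scaled = np.clip(scaled, 0.0, 1.0)
    return scaled


def inverse_minmax(scaled: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Inverse affine map; degenerate features return their constant."""
    scaled = np.asarray(scaled, dtype=float)
    out = scaled * (params.maxs - params.mins) + params.mins
    out[..., params.degenerate] = params.mins[params.degenerate]
    return out


@dataclass
class ImputationParams:
    """Per-feature fill values: numeric median, nominal mode."""

    fills: Dict[str, float]
    counts: Dict[str, int] = field(default_factory=dict)  # cells imputed at fit


def fit_imputer(train: TabularDataset) -> ImputationParams:
    vals = train.values
    fills: Dict[str, float] = {}
    counts: Dict[str, int] = {}
    for j, spec in enumerate(train.schema.predictors):
        col = vals[:, j]
        present = col[~np.isnan(col)]
        if present.size == 0:
            raise ValidationError(f"feature {spec.name!r} is entirely missing")
        if spec.is_numeric:
            fills[spec.name] = float(np.median(present))
        else:
            codes, freq = np.unique(present, return_counts=True)
            fills[spec.name] = float(codes[np.argmax(freq)])  # ties -> lowest code
        counts[spec.name] = int(np.isnan(col).sum())
    return ImputationParams(fills, counts)


def apply_imputer(ds: TabularDataset, params: ImputationParams) -> TabularDataset:
    vals = ds.values.copy()
    for j, spec in enumerate(ds.schema.predictors):
        col = vals[:, j]
        col[np.isnan(col)] = params.fills[spec.name]
    return ds.with_values(vals)


def impute_missing(ds: TabularDataset) -> TabularDataset:
    """Fill missing cells with the dataset's own median/mode (idempotent)."""
    return apply_imputer(ds, fit_imputer(ds))


def flag_outliers(ds: TabularDataset) -> np.ndarray:
    """Tukey fence mask: numeric cells outside [Q1-1.5*IQR, Q3+1.5*IQR].

    Quartiles use linear interpolation between order statistics.  Nominal
    features are never flagged; the mask is report-only, rows are not dropped.
    """
    vals = ds.values
    mask = np.zeros_like(vals, dtype=bool)
    for j, spec in enumerate(ds.schema.predictors):
        if not spec.is_numeric:
            continue
        col = vals[:, j]
        present = ~np.isnan(col)
        if present.sum() == 0:
            continue
        q1, q3 = np.quantile(col[present], [0.25, 0.75], method="linear")
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        mask[:, j] = present & ((col < lo) | (col > hi))
    return mask
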