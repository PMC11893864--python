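"""CSV reading/writing and stratified splitting.

Columns are matched to the schema by header name, not position, so files with
reordered columns load identically.  Values round-trip exactly: nominal codes
are written as integers and numeric values with shortest round-trip repr.
"""

from __future__ import annotations

import os
from typing import Tuple

import numpy as np
import pandas as pd

from .errors import IOError_, ParseError, SchemaError, ValidationError
from .schema import FeatureSchema, TabularDataset


def load_dataset(path, schema: FeatureSchema, require_labels: bool = True,
                 ) -> TabularDataset:
    """Read a header CSV into a validated :class:`TabularDataset`.

    Missing required columns raise :class:`SchemaError` naming the column;
    unparseable cells raise :class:`ParseError` with row and column.  A
    validation report flagging out-of-domain cells is attached to the result.
    """
    if not os.path.exists(path):
        raise IOError_(f"no such file: {path}")
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    raw.columns = [c.strip() for c in raw.columns]
    missing = [n for n in schema.predictor_names if n not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    has_target = schema.target.name in raw.columns
    if require_labels and not has_target:
        raise SchemaError(f"missing required column(s): {schema.target.name}")

    def parse_column(name: str) -> np.ndarray:
        col = raw[name]
        out = np.empty(len(col), dtype=float)
        for row, cell in enumerate(col):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) \
                    or str(cell).strip() == "":
                out[row] = np.nan
                continue
            try:
                # float() is correctly rounded, so written values reload exactly
                out[row] = float(cell)
            except ValueError:
                raise ParseError(f"unparseable cell at row {row}, column "
                                 f"{name!r}: {cell!r}") from None
        return out

    frame = pd.DataFrame(
        {n: parse_column(n) for n in schema.predictor_names},
        columns=schema.predictor_names)
    labels = None
    if has_target:
        tvals = parse_column(schema.target.name)
        if np.isnan(tvals).any():
            row = int(np.flatnonzero(np.isnan(tvals))[0])
            raise ParseError(f"missing target value at row {row}")
        bad = [v for v in np.unique(tvals) if int(v) not in schema.target.domain
               or not float(v).is_integer()]
        if bad:
            raise SchemaError(f"target codes outside {schema.target.domain}: {bad}")
        labels = tvals.astype(int)
    ds = TabularDataset(frame, labels, schema)
    ds.validate()
    return ds


def write_dataset(ds: TabularDataset, path) -> None:
    """Write dataset (and labels if present) to a header CSV; exact round-trip."""
    out = ds.frame.copy()
    for spec in ds.schema.predictors:
        if not spec.is_numeric:
            col = out[spec.name]
            if col.notna().all() and (col == col.round()).all():
                out[spec.name] = col.astype(int)
    if ds.labels is not None:
        out[ds.schema.target.name] = ds.labels.astype(int)
    try:
        out.to_csv(path, index=False)
    except OSError as exc:
        raise IOError_(f"cannot write {path}: {exc}") from exc


def stratified_split(ds: TabularDataset, test_fraction: float, seed: int,
                     ) -> Tuple[TabularDataset, TabularDataset]:
    """Deterministic per-class split; test counts within 1 of the exact quota."""
    if not 0.0 < test_fraction < 1.0:
        raise ValidationError("test_fraction must lie strictly between 0 and 1")
    if ds.labels is None:
        raise ValidationError("stratified_split requires labels")
    classes = np.unique(ds.labels)
    if len(classes) < 2:
        raise ValidationError("both classes must be present to stratify")
    rng = np.random.default_rng(seed)
    test_idx = []
    for c in classes:
        rows = np.flatnonzero(ds.labels == c)
        rng.shuffle(rows)
        k = int(round(len(rows) * test_fraction))
        k = min(max(k, 1), len(rows) - 1)  # keep both parts non-empty per class
        test_idx.extend(rows[:k].tolist())
    test_idx = np.sort(np.asarray(test_idx, dtype=int))
    mask = np.zeros(ds.n, dtype=bool)
    mask[test_idx] = True
    train_idx = np.flatnonzero(~mask)
    return ds.subset(train_idx), ds.subset(test_idx)
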