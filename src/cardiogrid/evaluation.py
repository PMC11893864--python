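"""Confusion counts, the six classification metrics, unseen-data evaluation,
and hybrid-vs-standalone comparison tables.

Class 1 ("disease present") is the positive class.  Metrics are kept as
proportions in [0, 1]; ratios with zero denominators are explicit ``None``
markers with a reason — never silent zeros — so comparison tables cannot be
corrupted by undefined cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError
from .modeling import TrainedPipeline
from .schema import TabularDataset

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "sensitivity",
                "specificity")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_dict(self) -> dict:
        return {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn}


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Tally TP/TN/FP/FN with 1 as the positive class."""
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if t.shape != p.shape:
        raise ValidationError("y_true and y_pred must have equal length")
    if not (np.isin(t, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValidationError("labels must be binary 0/1")
    tp = int(np.sum((t == 1) & (p == 1)))
    tn = int(np.sum((t == 0) & (p == 0)))
    fp = int(np.sum((t == 0) & (p == 1)))
    fn = int(np.sum((t == 1) & (p == 0)))
    return ConfusionCounts(tp, tn, fp, fn)


@dataclass
class MetricsReport:
    accuracy: Optional[float]
    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    counts: ConfusionCounts
    undefined: Dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {m: getattr(self, m) for m in METRIC_NAMES}
        d["counts"] = self.counts.to_dict()
        d["undefined"] = dict(self.undefined)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"metric": m, "value": getattr(self, m)}
                             for m in METRIC_NAMES])


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, recall/sensitivity, F1 and specificity from counts."""
    if c.total == 0:
        raise ValidationError("cannot compute metrics on zero records")
    undefined: Dict[str, str] = {}

    def ratio(num: int, den: int, name: str, reason: str) -> Optional[float]:
        if den == 0:
            undefined[name] = reason
            return None
        return num / den

    accuracy = (c.tp + c.tn) / c.total
    precision = ratio(c.tp, c.tp + c.fp, "precision", "no positive predictions")
    recall = ratio(c.tp, c.tp + c.fn, "recall", "no positive ground truth")
    if recall is None:
        undefined["sensitivity"] = undefined["recall"]
    specificity = ratio(c.tn, c.fp + c.tn, "specificity",
                        "no negative ground truth")
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None
        undefined["f1"] = "precision/recall undefined or both zero"
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(accuracy, precision, recall, f1, recall, specificity,
                         c, undefined)


def evaluate(y_true, y_pred) -> MetricsReport:
    return metrics(confusion(y_true, y_pred))


def evaluate_unseen(pipeline: TrainedPipeline, unseen: TabularDataset,
                    ) -> Tuple[MetricsReport, ConfusionCounts]:
    """Apply a frozen bundle to new data without refitting anything."""
    if unseen.labels is None:
        raise ValidationError("unseen dataset must carry labels to evaluate")
    if unseen.schema.fingerprint() != pipeline.schema_fingerprint:
        raise SchemaError(
            "unseen dataset schema does not match the trained bundle; map the "
            "columns to the training schema first")
    y_pred, _ = pipeline.predict(unseen)
    rep = metrics(confusion(unseen.labels, y_pred))
    return rep, rep.counts


def comparison_report(results: List[Tuple[str, str, MetricsReport]],
                      ) -> pd.DataFrame:
    """Long-format (family, mode, metric, value) table with hybrid deltas.

    The returned frame has one row per family x mode x metric; the attribute
    ``attrs['deltas']`` holds per-family hybrid-minus-standalone differences
    for every metric defined in both modes.
    """
    if not results:
        raise ValidationError("at least one result is required")
    rows = []
    for mode, family, rep in results:
        for m in METRIC_NAMES:
            rows.append({"family": family, "mode": mode, "metric": m,
                         "value": getattr(rep, m)})
    table = pd.DataFrame(rows)
    deltas = []
    for family in table["family"].unique():
        sub = table[table["family"] == family]
        hybrid = sub[sub["mode"] == "hybrid"].set_index("metric")["value"]
        stand = sub[sub["mode"] == "standalone"].set_index("metric")["value"]
        for m in METRIC_NAMES:
            if m in hybrid.index and m in stand.index and \
                    hybrid[m] is not None and stand[m] is not None:
                deltas.append({"family": family, "metric": m,
                               "delta": hybrid[m] - stand[m]})
    table.attrs["deltas"] = pd.DataFrame(deltas)
    return table
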