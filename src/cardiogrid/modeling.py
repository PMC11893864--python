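"""Feature fusion, tuned classical classifiers, and the frozen pipeline bundle.

The fused design matrix concatenates the normalized tabular block with the
frozen-backbone deep block, column-wise, tabular first.  Six classifier
families are tuned by exhaustive grid search under stratified k-fold
cross-validation (default 5 folds, accuracy scoring, ties broken by declared
grid order), then refit on all training rows.  A standalone mode omits the
deep block but shares the identical CV machinery, so hybrid-vs-standalone
scores are paired fold by fold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import joblib
import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import SchemaError, ValidationError
from .feature_extraction import ToyBackbone, extract_features, make_toy_backbone
from .preprocessing import (ImputationParams, NormalizationParams, apply_imputer,
                            apply_minmax, fit_imputer, fit_minmax)
from .schema import TabularDataset
from .tab2img import FeatureOrder, compute_feature_order, convert_dataset

BUNDLE_VERSION = 1

FAMILIES = ("random_forest", "logistic_regression", "decision_tree", "knn",
            "gradient_boosting", "svm")

#: Default grids: supersets containing each published best configuration.
DEFAULT_GRIDS: Dict[str, Dict[str, list]] = {
    "random_forest": {"n_estimators": [50, 100, 200],
                      "max_depth": [None, 5, 10]},
    "logistic_regression": {"C": [0.1, 1, 10], "solver": ["liblinear"]},
    "decision_tree": {"max_depth": [None, 5, 10], "min_samples_split": [2, 5]},
    "knn": {"n_neighbors": [3, 5, 7], "weights": ["uniform", "distance"]},
    "gradient_boosting": {"learning_rate": [0.05, 0.1, 0.2],
                          "n_estimators": [50, 100]},
    "svm": {"C": [0.1, 1, 10], "kernel": ["linear", "rbf"]},
}


def _make_estimator(family: str, seed: int):
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if family == "logistic_regression":
        return LogisticRegression(max_iter=5000, random_state=seed)
    if family == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if family == "knn":
        return KNeighborsClassifier()
    if family == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed)
    if family == "svm":
        return SVC(random_state=seed)
    raise ValidationError(f"unknown classifier family {family!r}")


@dataclass
class FusedMatrix:
    """Column blocks: tabular first, then deep features."""

    values: np.ndarray
    n_tab: int
    n_deep: int

    def __post_init__(self) -> None:
        if self.values.shape[1] != self.n_tab + self.n_deep:
            raise ValidationError("column count must equal n_tab + n_deep")

    @property
    def block_labels(self) -> np.ndarray:
        return np.array(["tabular"] * self.n_tab + ["deep"] * self.n_deep)


def fuse(tab_scaled: np.ndarray, deep: Optional[np.ndarray] = None) -> FusedMatrix:
    tab = np.asarray(tab_scaled, dtype=float)
    if deep is None or (hasattr(deep, "shape") and deep.shape[-1] == 0):
        return FusedMatrix(tab.copy(), tab.shape[1], 0)
    deep = np.asarray(deep, dtype=float)
    if deep.shape[0] != tab.shape[0]:
        raise ValidationError(
            f"row mismatch: tabular {tab.shape[0]} vs deep {deep.shape[0]}")
    return FusedMatrix(np.hstack([tab, deep]), tab.shape[1], deep.shape[1])


@dataclass
class HybridModelSpec:
    family: str
    grid: Dict[str, list] = None
    scoring: str = "accuracy"
    folds: int = 5

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown family {self.family!r}")
        if self.grid is None:
            self.grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.family].items()}
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ValidationError("hyperparameter grid must be non-empty")
        if self.folds < 2:
            raise ValidationError("fold count must be >= 2")

    def candidates(self) -> List[dict]:
        """Cartesian product in declared order (first-declared wins ties)."""
        keys = list(self.grid)
        return [dict(zip(keys, combo))
                for combo in itertools.product(*(self.grid[k] for k in keys))]


def tune_and_train(fused: FusedMatrix, labels: np.ndarray, spec: HybridModelSpec,
                   seed: int) -> Tuple[object, dict, pd.DataFrame]:
    """Exhaustive stratified-CV grid search; refit best candidate on all rows.

    Returns ``(fitted_estimator, chosen_params, cv_table)`` where the CV table
    has one row per (candidate, fold) with its accuracy.
    """
    x = fused.values
    y = np.asarray(labels).astype(int)
    uniq, counts = np.unique(y, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("both classes must be present for training")
    if counts.min() < spec.folds:
        raise ValidationError(
            f"smallest class has {counts.min()} rows < {spec.folds} folds; "
            "reduce the fold count")
    skf = StratifiedKFold(n_splits=spec.folds, shuffle=True, random_state=seed)
    folds = list(skf.split(x, y))
    rows = []
    means = []
    candidates = spec.candidates()
    for ci, params in enumerate(candidates):
        scores = []
        for fi, (tr, te) in enumerate(folds):
            est = clone(_make_estimator(spec.family, seed)).set_params(**params)
            est.fit(x[tr], y[tr])
            acc = float(np.mean(est.predict(x[te]) == y[te]))
            scores.append(acc)
            rows.append({"family": spec.family, "candidate": ci,
                         "params": repr(params), "fold": fi, "score": acc})
        means.append(float(np.mean(scores)))
    best = int(np.argmax(means))  # argmax returns the first maximum: declared order
    chosen = candidates[best]
    final = clone(_make_estimator(spec.family, seed)).set_params(**chosen)
    final.fit(x, y)
    table = pd.DataFrame(rows)
    table.attrs["best_candidate"] = best
    table.attrs["best_mean_score"] = means[best]
    return final, chosen, table


@dataclass
class TrainedPipeline:
    """Frozen bundle: every fitted stage needed to score raw records."""

    schema_fingerprint: str
    schema_dict: dict
    impute_params: ImputationParams
    norm_params: NormalizationParams
    order: Optional[FeatureOrder]          # None in standalone mode
    backbone: Optional[ToyBackbone]        # None in standalone mode
    target_side: int
    estimator: object
    model_spec: HybridModelSpec
    chosen_params: dict
    cv_table: pd.DataFrame
    cv_score: float
    seed: int
    mode: str = "hybrid"                   # "hybrid" | "standalone"
    paper_mode: bool = False
    extra: dict = field(default_factory=dict)

    # -- scoring ------------------------------------------------------------

    def _check_schema(self, ds: TabularDataset) -> None:
        if ds.schema.fingerprint() != self.schema_fingerprint:
            raise SchemaError("dataset schema does not match the trained bundle")

    def transform_matrix(self, values: np.ndarray, chunk: int = 4096) -> np.ndarray:
        """Raw predictor matrix -> fused design matrix (chunked for memory)."""
        values = np.asarray(values, dtype=float)
        if values.ndim == 1:
            values = values[None, :]
        out = []
        for start in range(0, len(values), chunk):
            block = values[start: start + chunk]
            scaled = apply_minmax(block, self.norm_params)
            if self.mode == "hybrid":
                images = convert_dataset(scaled, self.order, self.target_side)
                deep = extract_features(images, self.backbone)
            else:
                deep = None
            out.append(fuse(scaled, deep).values)
        return np.vstack(out)

    def score_matrix(self, values: np.ndarray) -> np.ndarray:
        """Class-1 score (probability when available) per raw record."""
        fusedv = self.transform_matrix(values)
        if hasattr(self.estimator, "predict_proba"):
            return self.estimator.predict_proba(fusedv)[:, 1]
        return self.estimator.decision_function(fusedv)

    def predict(self, raw: TabularDataset):
        """Apply the frozen pipeline end to end: (labels, class-1 scores)."""
        self._check_schema(raw)
        ds = apply_imputer(raw, self.impute_params)
        fusedv = self.transform_matrix(ds.values)
        labels = self.estimator.predict(fusedv).astype(int)
        if hasattr(self.estimator, "predict_proba"):
            scores = self.estimator.predict_proba(fusedv)[:, 1]
        else:
            scores = self.estimator.decision_function(fusedv)
        return labels, scores

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        bundle = {
            "version": BUNDLE_VERSION,
            "schema_fingerprint": self.schema_fingerprint,
            "schema": self.schema_dict,
            "impute": {"fills": self.impute_params.fills,
                       "counts": self.impute_params.counts},
            "normalization": {
                "feature_names": self.norm_params.feature_names,
                "mins": self.norm_params.mins, "maxs": self.norm_params.maxs,
                "clip": self.norm_params.clip},
            "order": None if self.order is None else {
                "order": list(self.order.order),
                "distance": self.order.distance,
                "linkage_method": self.order.linkage_method,
                "fingerprint": self.order.fingerprint},
            "backbone": None if self.backbone is None else self.backbone.to_dict(),
            "target_side": self.target_side,
            "estimator": self.estimator,
            "model_spec": {"family": self.model_spec.family,
                           "grid": self.model_spec.grid,
                           "scoring": self.model_spec.scoring,
                           "folds": self.model_spec.folds},
            "chosen_params": self.chosen_params,
            "cv_table": self.cv_table,
            "cv_score": self.cv_score,
            "seed": self.seed,
            "mode": self.mode,
            "paper_mode": self.paper_mode,
            "extra": self.extra,
        }
        joblib.dump(bundle, path)

    @classmethod
    def load(cls, path) -> "TrainedPipeline":
        b = joblib.load(path)
        if b.get("version") != BUNDLE_VERSION:
            raise ValidationError(f"unsupported bundle version {b.get('version')}")
        order = None
        if b["order"] is not None:
            order = FeatureOrder(tuple(b["order"]["order"]), b["order"]["distance"],
                                 b["order"]["linkage_method"],
                                 b["order"]["fingerprint"])
        backbone = None
        if b["backbone"] is not None:
            backbone = ToyBackbone.from_dict(b["backbone"])
        return cls(
            schema_fingerprint=b["schema_fingerprint"],
            schema_dict=b["schema"],
            impute_params=ImputationParams(b["impute"]["fills"],
                                           b["impute"]["counts"]),
            norm_params=NormalizationParams(
                b["normalization"]["feature_names"], b["normalization"]["mins"],
                b["normalization"]["maxs"], b["normalization"]["clip"]),
            order=order, backbone=backbone, target_side=b["target_side"],
            estimator=b["estimator"],
            model_spec=HybridModelSpec(**b["model_spec"]),
            chosen_params=b["chosen_params"], cv_table=b["cv_table"],
            cv_score=b["cv_score"], seed=b["seed"], mode=b["mode"],
            paper_mode=b["paper_mode"], extra=b.get("extra", {}))


def train_pipeline(train: TabularDataset, spec: HybridModelSpec, seed: int,
                   mode: str = "hybrid", target_side: int = 224,
                   backbone: Optional[ToyBackbone] = None,
                   distance: str = "signed", linkage_method: str = "average",
                   paper_mode: bool = False,
                   full_data: Optional[TabularDataset] = None) -> TrainedPipeline:
    """Fit every stage on the training rows and tune the classifier.

    In the default (leakage-safe) mode imputation, normalization and the
    feature order are fitted on ``train`` only.  With ``paper_mode=True`` and
    ``full_data`` supplied, those stages are fitted on the full dataset, which
    mirrors the published procedure where leakage control is unstated.
    """
    if train.labels is None:
        raise ValidationError("training dataset must be labeled")
    if mode not in ("hybrid", "standalone"):
        raise ValidationError(f"unknown mode {mode!r}")
    fit_ds = full_data if (paper_mode and full_data is not None) else train
    impute = fit_imputer(fit_ds)
    train_imp = apply_imputer(train, impute)
    fit_imp = apply_imputer(fit_ds, impute)
    norm = fit_minmax(fit_imp)
    train_scaled = apply_minmax(train_imp, norm)
    order = None
    bb = None
    deep = None
    if mode == "hybrid":
        fit_scaled = apply_minmax(fit_imp, norm)
        order = compute_feature_order(fit_scaled, train.schema,
                                      distance=distance,
                                      linkage_method=linkage_method)
        bb = backbone if backbone is not None else make_toy_backbone(
            seed, input_side=target_side)
        if bb.spec.input_side != target_side:
            raise ValidationError("backbone expected side != target_side")
        # backbone is frozen: extracting once before CV leaks no labels
        images = convert_dataset(train_scaled, order, target_side)
        deep = extract_features(images, bb)
    fusedm = fuse(train_scaled, deep)
    estimator, chosen, cv_table = tune_and_train(fusedm, train.labels, spec, seed)
    return TrainedPipeline(
        schema_fingerprint=train.schema.fingerprint(),
        schema_dict=train.schema.to_dict(),
        impute_params=impute, norm_params=norm, order=order, backbone=bb,
        target_side=target_side, estimator=estimator, model_spec=spec,
        chosen_params=chosen, cv_table=cv_table,
        cv_score=float(cv_table.attrs["best_mean_score"]), seed=seed, mode=mode,
        paper_mode=paper_mode)


def train_standalone(train: TabularDataset, spec: HybridModelSpec, seed: int,
                     **kwargs) -> TrainedPipeline:
    """Tabular-only twin of :func:`train_pipeline` (d_cnn = 0)."""
    return train_pipeline(train, spec, seed, mode="standalone", **kwargs)
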