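"""Synthetic tabular data: a class-conditional Gaussian-copula generator and
the quality-evaluation protocol (correlation MAE, 50:50 baseline split, and
per-feature Kolmogorov-Smirnov / chi-square tests with the 0.05 cutoff).

Generator model
---------------
Records are sampled per target class, proportionally to class prevalence.
Within a class, a latent standard-normal vector with a fitted correlation
matrix is pushed through per-feature marginals: numeric features through the
inverse empirical CDF (linear interpolation between order statistics),
nominal features by thresholding the latent normal at the cumulative
category frequencies.  The latent correlation matrix is estimated from
rank-based normal scores (van der Waerden scores for numerics; truncated
normal conditional means per category bin for nominals) with a
polyserial-style moment correction, then repaired to positive semi-definite
by eigenvalue clipping.  A neural CTGAN could sit behind the same contract;
the copula backend is the deterministic default.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import chi2_contingency, ks_2samp, norm, rankdata

from .errors import ValidationError
from .schema import FeatureSchema, TabularDataset, dataset_from_arrays

_QUANTILE_GRID = 1024  # resolution for parametric marginals stored as quantiles


# ---------------------------------------------------------------------------
# generator model


@dataclass
class ClassModel:
    """Marginals + latent correlation for one target class."""

    numeric_quantiles: Dict[str, np.ndarray]       # sorted sample values
    nominal_freqs: Dict[str, Dict[int, float]]     # code -> probability
    latent_corr: np.ndarray                        # (d, d) PSD, unit diagonal


@dataclass
class GeneratorModel:
    schema: FeatureSchema
    class_probs: Dict[int, float]
    classes: Dict[int, ClassModel]
    fit_seed: Optional[int] = None

    def __post_init__(self) -> None:
        for c, m in self.classes.items():
            m.latent_corr = repair_correlation(m.latent_corr)
            for name, fr in m.nominal_freqs.items():
                tot = sum(fr.values())
                if not np.isclose(tot, 1.0):
                    raise ValidationError(
                        f"frequencies for {name!r} (class {c}) sum to {tot}")


def repair_correlation(r: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Symmetrize, eigen-clip to PSD, and rescale to unit diagonal."""
    r = np.asarray(r, dtype=float)
    r = (r + r.T) / 2.0
    vals, vecs = np.linalg.eigh(r)
    if vals.min() < floor:
        vals = np.clip(vals, floor, None)
        r = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(r))
        r = r / np.outer(d, d)
        r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return r


def _latent_scores(col: np.ndarray, spec) -> np.ndarray:
    """Rank-based normal scores used for latent-correlation estimation."""
    n = len(col)
    if spec.is_numeric:
        u = (rankdata(col, method="average") - 0.5) / n
        return ndtri(u)
    # nominal: truncated-normal conditional mean of each category's latent bin
    codes, counts = np.unique(col, return_counts=True)
    cum = np.concatenate([[0.0], np.cumsum(counts) / n])
    lo, hi = ndtri(np.clip(cum[:-1], 1e-12, None)), ndtri(np.minimum(cum[1:], 1 - 1e-12))
    p = counts / n
    m = (norm.pdf(lo) - norm.pdf(hi)) / p
    lookup = dict(zip(codes, m))
    return np.array([lookup[v] for v in col])


def _estimate_latent_corr(values: np.ndarray, schema: FeatureSchema) -> np.ndarray:
    d = values.shape[1]
    scores = np.empty_like(values, dtype=float)
    variances = np.empty(d)
    for j, spec in enumerate(schema.predictors):
        col = values[:, j]
        if np.all(col == col[0]):
            scores[:, j] = 0.0
            variances[j] = 0.0
            continue
        s = _latent_scores(col, spec)
        scores[:, j] = s
        variances[j] = s.var()
    r = np.eye(d)
    cov = np.cov(scores, rowvar=False, ddof=0)
    cov = np.atleast_2d(cov)
    for i in range(d):
        for j in range(i + 1, d):
            if variances[i] == 0 or variances[j] == 0:
                continue
            r[i, j] = r[j, i] = np.clip(
                cov[i, j] / (variances[i] * variances[j]), -1.0, 1.0)
    return r


def fit_generator(reference: TabularDataset, seed: int) -> GeneratorModel:
    """Fit the copula generator to a labeled reference dataset."""
    if reference.labels is None:
        raise ValidationError("fit_generator requires a labeled reference dataset")
    if reference.n < 30:
        warnings.warn(f"reference has only {reference.n} rows; fits below ~30 "
                      "rows are unreliable")
    schema = reference.schema
    vals = reference.values
    if np.isnan(vals).any():
        raise ValidationError("impute missing values before fitting the generator")
    classes: Dict[int, ClassModel] = {}
    labels = reference.labels.astype(int)
    uniq, counts = np.unique(labels, return_counts=True)
    class_probs = {int(c): float(k) / reference.n for c, k in zip(uniq, counts)}
    for c in uniq:
        sub = vals[labels == c]
        nq: Dict[str, np.ndarray] = {}
        nf: Dict[str, Dict[int, float]] = {}
        for j, spec in enumerate(schema.predictors):
            col = sub[:, j]
            if np.all(col == col[0]):
                warnings.warn(f"feature {spec.name!r} constant in class {c}; "
                              "degenerate marginal")
            if spec.is_numeric:
                nq[spec.name] = np.sort(col)
            else:
                codes, freq = np.unique(col.astype(int), return_counts=True)
                nf[spec.name] = {int(k): float(v) / len(col)
                                 for k, v in zip(codes, freq)}
        latent = _estimate_latent_corr(sub, schema)
        classes[int(c)] = ClassModel(nq, nf, latent)
    return GeneratorModel(schema, class_probs, classes, fit_seed=int(seed))


def _class_counts(probs: Dict[int, float], n: int) -> Dict[int, int]:
    """Largest-remainder allocation of n rows to classes."""
    items = sorted(probs.items())
    raw = {c: p * n for c, p in items}
    base = {c: int(np.floor(v)) for c, v in raw.items()}
    rem = n - sum(base.values())
    order = sorted(items, key=lambda cp: raw[cp[0]] - base[cp[0]], reverse=True)
    for c, _ in order[:rem]:
        base[c] += 1
    return base


def sample(model: GeneratorModel, n: int = 1100, seed: int = 0) -> TabularDataset:
    """Draw n schema-valid labeled records; identical seed -> identical table."""
    if n <= 0:
        raise ValidationError("sample size must be positive")
    rng = np.random.default_rng(seed)
    schema = model.schema
    d = schema.n_predictors
    counts = _class_counts(model.class_probs, n)
    blocks, label_blocks = [], []
    for c in sorted(model.classes):
        k = counts.get(c, 0)
        if k == 0:
            continue
        cm = model.classes[c]
        chol = np.linalg.cholesky(repair_correlation(cm.latent_corr) +
                                  1e-10 * np.eye(d))
        z = rng.standard_normal((k, d)) @ chol.T
        u = ndtr(z)
        out = np.empty((k, d))
        for j, spec in enumerate(schema.predictors):
            if spec.is_numeric:
                out[:, j] = np.quantile(cm.numeric_quantiles[spec.name], u[:, j],
                                        method="linear")
            else:
                fr = cm.nominal_freqs[spec.name]
                codes = np.array(sorted(fr))
                cum = np.cumsum([fr[int(cc)] for cc in codes])
                idx = np.searchsorted(cum, u[:, j], side="left")
                out[:, j] = codes[np.minimum(idx, len(codes) - 1)]
        blocks.append(out)
        label_blocks.append(np.full(k, c, dtype=int))
    values = np.vstack(blocks)
    labels = np.concatenate(label_blocks)
    perm = rng.permutation(n)
    return dataset_from_arrays(values[perm], labels[perm], schema)


# ---------------------------------------------------------------------------
# quality evaluation


def _corr_with_const_zero(values: np.ndarray) -> np.ndarray:
    sd = values.std(axis=0)
    const = sd == 0
    if const.any():
        warnings.warn("constant feature(s) present; their correlations are "
                      "treated as 0")
    safe = values.copy()
    if const.any():
        safe[:, const] = np.arange(len(values))[:, None]
    r = np.atleast_2d(np.corrcoef(safe, rowvar=False))
    r[const, :] = 0.0
    r[:, const] = 0.0
    np.fill_diagonal(r, 1.0)
    return r


def correlation_mae(real: TabularDataset, synth: TabularDataset):
    """Per-feature mean |corr_real - corr_synth| over partner features + mean.

    Returns ``(per_feature, average)`` where ``per_feature`` is a pandas
    Series indexed by predictor name.
    """
    if real.schema.fingerprint() != synth.schema.fingerprint():
        raise ValidationError("datasets must share a schema")
    r1 = _corr_with_const_zero(real.values)
    r2 = _corr_with_const_zero(synth.values)
    diff = np.abs(r1 - r2)
    d = diff.shape[0]
    off = ~np.eye(d, dtype=bool)
    per = diff[off].reshape(d, d - 1).mean(axis=1) if d > 1 else np.zeros(d)
    series = pd.Series(per, index=real.schema.predictor_names, name="corr_mae")
    return series, float(series.mean())


def baseline_split_mae(ds: TabularDataset, seed: int) -> float:
    """Average correlation MAE between two random halves of one dataset."""
    if ds.n < 4:
        raise ValidationError("need at least 4 rows for a 50:50 baseline split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ds.n)
    half = ds.n // 2
    a, b = ds.subset(perm[:half]), ds.subset(perm[half: 2 * half])
    _, avg = correlation_mae(a, b)
    return avg


def _merge_small_expected(table: np.ndarray) -> np.ndarray:
    """Pool categories until every expected count is >= 5 (or 2 remain).

    Categories are merged smallest-pooled-count-first, a fixed documented
    rule that keeps the asymptotic chi-square valid on sparse tables.
    """
    tab = table.copy()
    while tab.shape[1] > 2:
        colsum = tab.sum(axis=0)
        expected = np.outer(tab.sum(axis=1), colsum) / tab.sum()
        if (expected >= 5).all():
            break
        order = np.argsort(colsum)
        i, j = order[0], order[1]
        tab[:, j] += tab[:, i]
        tab = np.delete(tab, i, axis=1)
    return tab


def distribution_tests(real: TabularDataset, synth: TabularDataset) -> pd.DataFrame:
    """Per-feature two-sample tests: KS for numerics, chi-square for nominals."""
    if real.schema.fingerprint() != synth.schema.fingerprint():
        raise ValidationError("datasets must share a schema")
    rows = []
    rv, sv = real.values, synth.values
    for j, spec in enumerate(real.schema.predictors):
        a, b = rv[:, j], sv[:, j]
        if spec.is_numeric:
            res = ks_2samp(a, b)
            rows.append({"feature": spec.name, "kind": "numeric", "test": "ks",
                         "statistic": float(res.statistic),
                         "pvalue": float(res.pvalue), "note": ""})
        else:
            codes = sorted(set(np.unique(a)) | set(np.unique(b)))
            if len(codes) < 2:
                rows.append({"feature": spec.name, "kind": "nominal",
                             "test": "chi2", "statistic": np.nan,
                             "pvalue": np.nan,
                             "note": "single observed category; test skipped"})
                continue
            table = np.array([[np.sum(a == c) for c in codes],
                              [np.sum(b == c) for c in codes]], dtype=float)
            merged = _merge_small_expected(table)
            note = "" if merged.shape[1] == table.shape[1] else (
                f"merged {table.shape[1] - merged.shape[1]} low-expectation "
                "category(ies)")
            if (merged.sum(axis=0) == 0).any() or merged.shape[1] < 2:
                rows.append({"feature": spec.name, "kind": "nominal",
                             "test": "chi2", "statistic": np.nan,
                             "pvalue": np.nan, "note": "degenerate table; skipped"})
                continue
            stat, p, _, _ = chi2_contingency(merged, correction=False)
            rows.append({"feature": spec.name, "kind": "nominal", "test": "chi2",
                         "statistic": float(stat), "pvalue": float(p),
                         "note": note})
    return pd.DataFrame(rows)


@dataclass
class QualityReport:
    """Aggregate of correlation, baseline-split, and distribution analyses."""

    per_feature_mae: pd.Series
    average_mae: float
    baseline_mae: float
    tests: pd.DataFrame
    cutoff: float = 0.05
    notes: list = field(default_factory=list)

    @property
    def passes(self) -> pd.Series:
        """Feature passes iff its test p-value >= cutoff."""
        return pd.Series(
            (self.tests["pvalue"] >= self.cutoff).to_numpy(),
            index=self.tests["feature"].to_numpy(), name="pass")

    def to_dict(self) -> dict:
        return {
            "average_mae": self.average_mae,
            "baseline_mae": self.baseline_mae,
            "cutoff": self.cutoff,
            "per_feature_mae": {k: float(v)
                                for k, v in self.per_feature_mae.items()},
            "tests": self.tests.to_dict(orient="records"),
            "notes": list(self.notes),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "QualityReport":
        with open(path) as fh:
            d = json.load(fh)
        tests = pd.DataFrame(d["tests"])
        per = pd.Series(d["per_feature_mae"], name="corr_mae")
        return cls(per, d["average_mae"], d["baseline_mae"], tests,
                   d["cutoff"], d.get("notes", []))

    def to_tsv(self, path) -> None:
        rows = []
        for name, v in self.per_feature_mae.items():
            rows.append({"feature": name, "metric": "corr_mae", "value": v,
                         "pass": ""})
        rows.append({"feature": "__all__", "metric": "average_corr_mae",
                     "value": self.average_mae, "pass": ""})
        rows.append({"feature": "__all__", "metric": "baseline_split_mae",
                     "value": self.baseline_mae, "pass": ""})
        for _, r in self.tests.iterrows():
            rows.append({"feature": r["feature"], "metric": f"{r['test']}_pvalue",
                         "value": r["pvalue"],
                         "pass": bool(r["pvalue"] >= self.cutoff)
                         if np.isfinite(r["pvalue"]) else ""})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def quality_report(real: TabularDataset, synth: TabularDataset, seed: int,
                   cutoff: float = 0.05) -> QualityReport:
    per, avg = correlation_mae(real, synth)
    base = baseline_split_mae(real, seed)
    tests = distribution_tests(real, synth)
    notes = [f"{r['feature']}: {r['note']}" for _, r in tests.iterrows()
             if r["note"]]
    return QualityReport(per, avg, base, tests, cutoff, notes)


# ---------------------------------------------------------------------------
# reference study conditions for the bundled heart schema

#: Within-class latent correlation structure for the reference generator.
#: Sparse, clinically signed couplings (e.g. thalach falls with age, ST
#: depression tracks exertional angina); declared once, repaired to PSD.
HEART_LATENT_COUPLINGS = {
    ("age", "thalach"): -0.40,
    ("age", "trestbps"): 0.30,
    ("age", "chol"): 0.20,
    ("age", "ca"): 0.30,
    ("oldpeak", "slope"): 0.45,
    ("oldpeak", "exang"): 0.30,
    ("cp", "exang"): -0.35,
    ("thalach", "exang"): -0.30,
    ("thalach", "slope"): -0.25,
    ("sex", "thal"): 0.25,
}

# per-class (0 = healthy, 1 = disease) marginal settings, UCI-like
_HEART_NUMERIC = {
    # name: {class: (dist, params)} -- norm: (mean, sd, lo, hi); gamma: (k, theta)
    "age": {0: ("norm", (56.6, 8.0, 29, 77)), 1: ("norm", (52.5, 9.6, 29, 77))},
    "trestbps": {0: ("norm", (134.4, 18.7, 94, 200)),
                 1: ("norm", (129.3, 16.2, 94, 200))},
    "chol": {0: ("norm", (251.1, 49.6, 126, 564)),
             1: ("norm", (242.2, 53.6, 126, 564))},
    "thalach": {0: ("norm", (139.1, 22.6, 71, 202)),
                1: ("norm", (158.5, 19.1, 71, 202))},
    "oldpeak": {0: ("gamma", (1.50, 1.06)), 1: ("gamma", (0.55, 1.05))},
}
_HEART_NOMINAL = {
    "sex": {0: {0: 0.17, 1: 0.83}, 1: {0: 0.45, 1: 0.55}},
    "cp": {0: {0: 0.73, 1: 0.08, 2: 0.13, 3: 0.06},
           1: {0: 0.25, 1: 0.25, 2: 0.40, 3: 0.10}},
    "fbs": {0: {0: 0.84, 1: 0.16}, 1: {0: 0.87, 1: 0.13}},
    "restecg": {0: {0: 0.56, 1: 0.40, 2: 0.04}, 1: {0: 0.37, 1: 0.59, 2: 0.04}},
    "exang": {0: {0: 0.45, 1: 0.55}, 1: {0: 0.86, 1: 0.14}},
    "slope": {0: {0: 0.09, 1: 0.65, 2: 0.26}, 1: {0: 0.05, 1: 0.35, 2: 0.60}},
    "ca": {0: {0: 0.33, 1: 0.32, 2: 0.22, 3: 0.13},
           1: {0: 0.79, 1: 0.12, 2: 0.06, 3: 0.03}},
    "thal": {0: {0: 0.01, 1: 0.08, 2: 0.26, 3: 0.65},
             1: {0: 0.01, 1: 0.03, 2: 0.76, 3: 0.20}},
}
_HEART_DISEASE_PREVALENCE = 0.51


def _parametric_quantiles(kind: str, params) -> np.ndarray:
    from scipy.stats import gamma as gamma_dist, truncnorm

    u = np.linspace(0.5 / _QUANTILE_GRID, 1 - 0.5 / _QUANTILE_GRID, _QUANTILE_GRID)
    if kind == "norm":
        mean, sd, lo, hi = params
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return truncnorm.ppf(u, a, b, loc=mean, scale=sd)
    k, theta = params
    return gamma_dist.ppf(u, k, scale=theta)


def heart_reference_model(schema: Optional[FeatureSchema] = None) -> GeneratorModel:
    """Reference generator for the bundled heart schema.

    Marginals and class frequencies emulate the public heart-disease tables;
    the within-class latent correlation is :data:`HEART_LATENT_COUPLINGS`.
    Used as the seeded ground-truth population in tests and desk-scale studies.
    """
    from .schema import heart_schema

    schema = schema or heart_schema()
    names = schema.predictor_names
    d = len(names)
    latent = np.eye(d)
    for (a, b), r in HEART_LATENT_COUPLINGS.items():
        i, j = names.index(a), names.index(b)
        latent[i, j] = latent[j, i] = r
    latent = repair_correlation(latent)
    classes = {}
    for c in (0, 1):
        nq = {n: _parametric_quantiles(*_HEART_NUMERIC[n][c])
              for n in schema.numeric_names}
        nf = {n: dict(_HEART_NOMINAL[n][c]) for n in schema.nominal_names}
        classes[c] = ClassModel(nq, nf, latent.copy())
    probs = {0: 1.0 - _HEART_DISEASE_PREVALENCE, 1: _HEART_DISEASE_PREVALENCE}
    return GeneratorModel(schema, probs, classes, fit_seed=None)
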