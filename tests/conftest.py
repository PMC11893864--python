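import numpy as np
import pytest

from cardiogrid.feature_extraction import make_toy_backbone
from cardiogrid.modeling import HybridModelSpec, train_pipeline
from cardiogrid.schema import (FeatureSchema, FeatureSpec, dataset_from_arrays,
                               heart_schema)
from cardiogrid.synthetic import heart_reference_model, sample


@pytest.fixture(scope="session")
def schema():
    return heart_schema()


@pytest.fixture(scope="session")
def reference_model(schema):
    return heart_reference_model(schema)


@pytest.fixture(scope="session")
def small_heart(reference_model):
    """200 labeled heart-like records sampled from the reference population."""
    return sample(reference_model, 200, seed=101)


def make_numeric_schema(d: int, low: float = 0.0, high: float = 1.0):
    """Ad-hoc all-numeric schema with d predictors (for small constructions)."""
    preds = tuple(FeatureSpec(f"x{i}", "numeric", (low, high)) for i in range(d))
    target = FeatureSpec("target", "nominal", (0, 1))
    return FeatureSchema(preds, target)


def separable_dataset(schema, n=200, seed=0, gap=0.6):
    """Two well-separated class-conditional clusters, schema-valid.

    The margin dwarfs the noise, so any linear separator attains zero CV
    errors on the scaled features.
    """
    rng = np.random.default_rng(seed)
    half = n // 2
    labels = np.array([0] * half + [1] * (n - half))
    vals = np.empty((n, schema.n_predictors))
    for j, spec in enumerate(schema.predictors):
        if spec.is_numeric:
            lo, hi = spec.domain
            span = hi - lo
            c0 = lo + 0.25 * span
            c1 = lo + (0.25 + gap) * span
            noise = rng.normal(0, 0.02 * span, size=n)
            vals[:, j] = np.clip(np.where(labels == 0, c0, c1) + noise, lo, hi)
        else:
            codes = spec.domain
            vals[:, j] = np.where(labels == 0, codes[0], codes[-1])
    return dataset_from_arrays(vals, labels, schema)


@pytest.fixture(scope="session")
def lr_pipeline(small_heart):
    """Small tuned hybrid logistic-regression pipeline (16 px toy backbone)."""
    backbone = make_toy_backbone(3, input_side=16)
    spec = HybridModelSpec("logistic_regression", grid={"C": [1.0],
                                                        "solver": ["liblinear"]})
    return train_pipeline(small_heart, spec, seed=5, target_side=16,
                          backbone=backbone)
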