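"""Fusion, grid-search cross-validation, and the frozen pipeline bundle."""

import numpy as np
import pytest

from cardiogrid.errors import SchemaError, ValidationError
from cardiogrid.feature_extraction import make_toy_backbone
from cardiogrid.modeling import (DEFAULT_GRIDS, FusedMatrix, HybridModelSpec,
                                 TrainedPipeline, fuse, train_pipeline,
                                 train_standalone, tune_and_train)

from conftest import separable_dataset


class TestFuse:
    def test_column_counts(self):
        rng = np.random.default_rng(0)
        fm = fuse(rng.random((10, 13)), rng.random((10, 32)))
        assert fm.values.shape == (10, 45)
        assert (fm.n_tab, fm.n_deep) == (13, 32)
        assert list(fm.block_labels[:13]) == ["tabular"] * 13

    def test_standalone_mode_is_tabular_block(self):
        tab = np.random.default_rng(1).random((5, 13))
        fm = fuse(tab, None)
        assert np.array_equal(fm.values, tab) and fm.n_deep == 0

    def test_rows_align(self):
        rng = np.random.default_rng(2)
        tab, deep = rng.random((6, 3)), rng.random((6, 4))
        fm = fuse(tab, deep)
        assert np.array_equal(fm.values[3], np.concatenate([tab[3], deep[3]]))

    def test_row_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="mismatch"):
            fuse(np.zeros((4, 2)), np.zeros((5, 2)))


class TestGridSearch:
    @pytest.fixture(scope="class")
    def toy_xy(self):
        rng = np.random.default_rng(3)
        y = np.array([0, 1] * 50)
        x = rng.normal(size=(100, 4)) + 3.0 * y[:, None]
        return FusedMatrix(x, 4, 0), y

    def test_single_candidate_selected(self, toy_xy):
        fm, y = toy_xy
        spec = HybridModelSpec("logistic_regression",
                               grid={"C": [0.5], "solver": ["liblinear"]})
        _, chosen, _ = tune_and_train(fm, y, spec, seed=0)
        assert chosen == {"C": 0.5, "solver": "liblinear"}

    def test_tie_breaks_to_first_declared(self, toy_xy):
        fm, y = toy_xy
        # two identical candidates must tie; the first declared wins
        spec = HybridModelSpec("logistic_regression",
                               grid={"C": [1.0, 1.0], "solver": ["liblinear"]})
        _, _, table = tune_and_train(fm, y, spec, seed=0)
        assert table.attrs["best_candidate"] == 0

    def test_cv_mean_recomputes_from_fold_table(self, toy_xy):
        fm, y = toy_xy
        spec = HybridModelSpec("decision_tree", grid={"max_depth": [2, None]})
        _, _, table = tune_and_train(fm, y, spec, seed=1)
        best = table.attrs["best_candidate"]
        recomputed = table[table.candidate == best].score.mean()
        assert recomputed == table.attrs["best_mean_score"]
        assert len(table) == 2 * spec.folds

    def test_chosen_params_in_declared_grid(self, toy_xy):
        fm, y = toy_xy
        spec = HybridModelSpec("random_forest",
                               grid={"n_estimators": [10, 20],
                                     "max_depth": [None, 3]})
        _, chosen, _ = tune_and_train(fm, y, spec, seed=2)
        assert chosen["n_estimators"] in (10, 20)
        assert chosen["max_depth"] in (None, 3)

    def test_seed_determinism(self, toy_xy):
        fm, y = toy_xy
        spec = HybridModelSpec("knn", grid={"n_neighbors": [3, 5]})
        r1 = tune_and_train(fm, y, spec, seed=7)
        r2 = tune_and_train(fm, y, spec, seed=7)
        assert r1[1] == r2[1]
        assert r1[2].score.tolist() == r2[2].score.tolist()

    def test_single_class_and_degenerate_folds_rejected(self, toy_xy):
        fm, _ = toy_xy
        with pytest.raises(ValidationError):
            tune_and_train(fm, np.zeros(100, dtype=int),
                           HybridModelSpec("knn"), seed=0)
        y_few = np.array([1] * 3 + [0] * 97)
        with pytest.raises(ValidationError, match="fold"):
            tune_and_train(fm, y_few, HybridModelSpec("knn"), seed=0)

    def test_default_grids_contain_published_optima(self):
        assert 50 in DEFAULT_GRIDS["random_forest"]["n_estimators"]
        assert None in DEFAULT_GRIDS["random_forest"]["max_depth"]
        assert 1 in DEFAULT_GRIDS["logistic_regression"]["C"]
        assert "liblinear" in DEFAULT_GRIDS["logistic_regression"]["solver"]
        assert 2 in DEFAULT_GRIDS["decision_tree"]["min_samples_split"]
        assert 5 in DEFAULT_GRIDS["knn"]["n_neighbors"]
        assert "uniform" in DEFAULT_GRIDS["knn"]["weights"]
        assert 0.1 in DEFAULT_GRIDS["gradient_boosting"]["learning_rate"]
        assert 0.1 in DEFAULT_GRIDS["svm"]["C"]
        assert "linear" in DEFAULT_GRIDS["svm"]["kernel"]


class TestPipelines:
    @pytest.fixture(scope="class")
    def separable(self, schema):
        return separable_dataset(schema, n=200, seed=0)

    def test_separable_data_reaches_perfect_cv_hybrid(self, separable):
        spec = HybridModelSpec("logistic_regression",
                               grid={"C": [1.0], "solver": ["liblinear"]})
        bb = make_toy_backbone(1, input_side=16)
        pipe = train_pipeline(separable, spec, seed=3, target_side=16,
                              backbone=bb)
        assert pipe.cv_score == 1.0
        labels, _ = pipe.predict(separable)
        assert np.array_equal(labels, separable.labels)

    def test_separable_data_reaches_perfect_cv_standalone(self, separable):
        spec = HybridModelSpec("logistic_regression",
                               grid={"C": [1.0], "solver": ["liblinear"]})
        pipe = train_standalone(separable, spec, seed=3)
        assert pipe.cv_score == 1.0
        assert pipe.mode == "standalone" and pipe.backbone is None

    def test_predict_deterministic_and_clipping_tolerant(self, lr_pipeline,
                                                         small_heart):
        l1, s1 = lr_pipeline.predict(small_heart)
        l2, s2 = lr_pipeline.predict(small_heart)
        assert np.array_equal(l1, l2) and np.array_equal(s1, s2)
        wild = small_heart.values.copy()
        wild[0, 0] = 119.0  # out of fitted range; clipped by normalization
        labels, _ = lr_pipeline.predict(small_heart.with_values(wild))
        assert labels.shape == (small_heart.n,)

    def test_schema_mismatch_rejected(self, lr_pipeline):
        from conftest import make_numeric_schema, separable_dataset
        other = separable_dataset(make_numeric_schema(13), n=20, seed=1)
        with pytest.raises(SchemaError):
            lr_pipeline.predict(other)

    def test_fitted_params_use_training_rows_only(self, small_heart, schema):
        """Anti-leakage: corrupting held-out rows leaves fitted params alone."""
        from cardiogrid.io import stratified_split
        train, test = stratified_split(small_heart, 0.3, seed=1)
        spec = HybridModelSpec("logistic_regression",
                               grid={"C": [1.0], "solver": ["liblinear"]})
        p1 = train_standalone(train, spec, seed=2)
        corrupted = test.with_values(test.values * 7.0 + 100.0)
        p2 = train_standalone(train, spec, seed=2)
        _ = p2.predict(small_heart.with_values(
            np.clip(small_heart.values, 0, 1e6)))
        assert np.array_equal(p1.norm_params.mins, p2.norm_params.mins)
        assert np.array_equal(p1.norm_params.maxs, p2.norm_params.maxs)
        assert corrupted.n + train.n == small_heart.n

    def test_bundle_roundtrip(self, tmp_path, lr_pipeline, small_heart):
        path = tmp_path / "bundle.joblib"
        lr_pipeline.save(path)
        back = TrainedPipeline.load(path)
        l1, s1 = lr_pipeline.predict(small_heart)
        l2, s2 = back.predict(small_heart)
        assert np.array_equal(l1, l2) and np.array_equal(s1, s2)
        assert back.chosen_params == lr_pipeline.chosen_params
        assert back.cv_score == lr_pipeline.cv_score
        assert back.order.order == lr_pipeline.order.order

    def test_paper_mode_fits_on_full_data(self, schema):
        full = separable_dataset(schema, n=80, seed=5)
        train = full.subset(range(60))
        spec = HybridModelSpec("logistic_regression",
                               grid={"C": [1.0], "solver": ["liblinear"]})
        p_default = train_standalone(train, spec, seed=1)
        p_paper = train_standalone(train, spec, seed=1, paper_mode=True,
                                   full_data=full)
        assert p_paper.paper_mode
        # paper-mode extremes come from all 80 rows, default from 60
        assert not np.array_equal(p_default.norm_params.maxs,
                                  p_paper.norm_params.maxs)
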