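"""Copula generator fitting/sampling and the quality-evaluation protocol."""

import numpy as np
import pytest

from cardiogrid.errors import ValidationError
from cardiogrid.schema import dataset_from_arrays
from cardiogrid.synthetic import (GeneratorModel, baseline_split_mae,
                                  correlation_mae, distribution_tests,
                                  fit_generator, quality_report,
                                  repair_correlation, sample)

from conftest import make_numeric_schema


def labeled(schema, values, seed=0):
    rng = np.random.default_rng(seed)
    return dataset_from_arrays(values, rng.integers(0, 2, len(values)), schema)


class TestFit:
    def test_duplicate_features_have_unit_latent_correlation(self):
        schema = make_numeric_schema(3, -100, 100)
        rng = np.random.default_rng(0)
        a = rng.normal(size=500)
        vals = np.column_stack([a, a, rng.normal(size=500)])
        model = fit_generator(labeled(schema, vals), seed=1)
        for cm in model.classes.values():
            assert cm.latent_corr[0, 1] == pytest.approx(1.0, abs=0.02)

    def test_independent_features_have_small_fitted_correlation(self):
        schema = make_numeric_schema(4, -100, 100)
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(5000, 4))
        model = fit_generator(labeled(schema, vals, seed=1), seed=1)
        for cm in model.classes.values():
            off = cm.latent_corr[~np.eye(4, dtype=bool)]
            assert np.abs(off).max() < 0.06  # ~3 sigma at n≈2500 per class

    def test_refit_same_seed_identical(self, small_heart):
        m1 = fit_generator(small_heart, seed=9)
        m2 = fit_generator(small_heart, seed=9)
        s1, s2 = sample(m1, 50, seed=3), sample(m2, 50, seed=3)
        assert np.array_equal(s1.values, s2.values)

    def test_small_reference_warns(self, schema, reference_model):
        tiny = sample(reference_model, 20, seed=0)
        with pytest.warns(UserWarning, match="unreliable"):
            fit_generator(tiny, seed=0)

    def test_psd_repair(self):
        r = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        fixed = repair_correlation(r)
        assert np.linalg.eigvalsh(fixed).min() >= 0
        assert np.allclose(np.diag(fixed), 1.0)


class TestSample:
    def test_default_sample_size_is_1100(self, reference_model):
        assert sample(reference_model, seed=0).n == 1100

    def test_schema_valid_and_seed_deterministic(self, reference_model):
        s1 = sample(reference_model, 300, seed=5)
        s2 = sample(reference_model, 300, seed=5)
        assert np.array_equal(s1.values, s2.values)
        assert np.array_equal(s1.labels, s2.labels)
        assert s1.validate().ok

    def test_bad_sample_size(self, reference_model):
        with pytest.raises(ValidationError):
            sample(reference_model, 0, seed=1)

    def test_degenerate_nominal_frequency(self, reference_model):
        import copy
        model = copy.deepcopy(reference_model)
        for cm in model.classes.values():
            cm.nominal_freqs["fbs"] = {0: 1.0}
        out = sample(model, 200, seed=2)
        j = model.schema.predictor_names.index("fbs")
        assert (out.values[:, j] == 0).all()

    def test_nominal_marginals_converge(self, reference_model):
        out = sample(reference_model, 10000, seed=11)
        names = reference_model.schema.predictor_names
        for feat in reference_model.schema.nominal_names:
            j = names.index(feat)
            col = out.values[out.labels == 1, j]
            target = reference_model.classes[1].nominal_freqs[feat]
            for code, p in target.items():
                assert np.mean(col == code) == pytest.approx(p, abs=0.03)


class TestCorrelationMae:
    def test_identical_tables_give_zero(self, small_heart):
        per, avg = correlation_mae(small_heart, small_heart)
        assert (per == 0).all() and avg == 0.0

    def test_three_feature_toy_matches_longhand(self):
        schema = make_numeric_schema(3, -100, 100)
        a = np.array([[1.0, 2.0, 1.0], [2.0, 1.0, 2.0], [3.0, 4.0, 2.0],
                      [4.0, 3.0, 4.0]])
        b = np.array([[1.0, 1.0, 4.0], [2.0, 3.0, 3.0], [3.0, 2.0, 2.0],
                      [4.0, 4.0, 1.0]])
        ra = np.corrcoef(a, rowvar=False)
        rb = np.corrcoef(b, rowvar=False)
        per, avg = correlation_mae(labeled(schema, a), labeled(schema, b))
        for i in range(3):
            expected = np.mean([abs(ra[i, j] - rb[i, j])
                                for j in range(3) if j != i])
            assert per.iloc[i] == pytest.approx(expected, abs=1e-12)
        assert avg == pytest.approx(per.mean())

    def test_symmetry(self, reference_model):
        a = sample(reference_model, 400, seed=1)
        b = sample(reference_model, 400, seed=2)
        _, ab = correlation_mae(a, b)
        _, ba = correlation_mae(b, a)
        assert ab == pytest.approx(ba, abs=1e-15)

    def test_constant_feature_warns_and_zeroes(self):
        schema = make_numeric_schema(2, 0, 10)
        a = np.column_stack([np.full(10, 5.0), np.arange(10.0)])
        b = np.column_stack([np.arange(10.0), np.arange(10.0)])
        with pytest.warns(UserWarning, match="constant"):
            per, _ = correlation_mae(labeled(schema, a), labeled(schema, b))
        assert np.isfinite(per).all()


class TestBaselineSplit:
    def test_duplicated_rows_give_zero_like_noise(self, reference_model):
        # i.i.d. data at n=10,000: split-half correlation MAE is sampling noise
        big = sample(reference_model, 10000, seed=21)
        assert baseline_split_mae(big, seed=3) < 0.05

    def test_deterministic(self, small_heart):
        assert baseline_split_mae(small_heart, seed=4) == \
            baseline_split_mae(small_heart, seed=4)

    def test_too_small_raises(self, small_heart):
        with pytest.raises(ValidationError):
            baseline_split_mae(small_heart.subset([0, 1, 2]), seed=1)


class TestDistributionTests:
    def test_identical_samples(self, small_heart):
        t = distribution_tests(small_heart, small_heart)
        num = t[t.kind == "numeric"]
        nom = t[(t.kind == "nominal") & t.pvalue.notna()]
        assert (num.statistic == 0).all() and (num.pvalue == 1).all()
        assert (nom.statistic == 0).all() and (nom.pvalue == 1).all()

    def test_disjoint_numeric_supports(self):
        schema = make_numeric_schema(1, -1000, 1000)
        a = labeled(schema, np.linspace(0, 1, 200)[:, None])
        b = labeled(schema, np.linspace(10, 11, 200)[:, None])
        t = distribution_tests(a, b)
        assert t.statistic.iloc[0] == 1.0
        assert t.pvalue.iloc[0] < 1e-6

    def test_single_category_skipped_with_note(self, reference_model):
        import copy
        model = copy.deepcopy(reference_model)
        for cm in model.classes.values():
            cm.nominal_freqs["fbs"] = {0: 1.0}
        a = sample(model, 200, seed=1)
        b = sample(model, 200, seed=2)
        t = distribution_tests(a, b).set_index("feature")
        assert "skipped" in t.loc["fbs", "note"]
        assert np.isnan(t.loc["fbs", "pvalue"])


class TestQualityReport:
    def test_identical_passes_everywhere(self, small_heart):
        rep = quality_report(small_heart, small_heart, seed=1)
        assert rep.average_mae == 0.0
        tested = rep.tests.pvalue.notna()
        assert rep.passes[tested.to_numpy()].all()

    def test_shifted_marginal_fails_ks(self, reference_model):
        real = sample(reference_model, 500, seed=1)
        synth = sample(reference_model, 500, seed=2)
        vals = synth.values.copy()
        j = reference_model.schema.predictor_names.index("thalach")
        vals[:, j] += 3 * real.values[:, j].std()  # 3 SD shift: KS has power ~1
        shifted = synth.with_values(vals)
        rep = quality_report(real, shifted, seed=1)
        t = rep.tests.set_index("feature")
        assert t.loc["thalach", "pvalue"] < 0.05
        assert not rep.passes["thalach"]

    def test_report_round_trips(self, tmp_path, reference_model):
        real = sample(reference_model, 300, seed=5)
        synth = sample(reference_model, 300, seed=6)
        rep = quality_report(real, synth, seed=2)
        path = tmp_path / "qr.json"
        rep.to_json(path)
        from cardiogrid.synthetic import QualityReport
        back = QualityReport.from_json(path)
        assert back.average_mae == rep.average_mae
        assert back.tests.pvalue.tolist() == pytest.approx(
            rep.tests.pvalue.tolist(), nan_ok=True)
        rep.to_tsv(tmp_path / "qr.tsv")
        assert (tmp_path / "qr.tsv").read_text().startswith("feature")


def test_generator_frequency_invariant():
    with pytest.raises(ValidationError, match="sum"):
        from cardiogrid.synthetic import ClassModel
        from cardiogrid.schema import heart_schema
        s = heart_schema()
        cm = ClassModel({n: np.array([0.0, 1.0]) for n in s.numeric_names},
                        {n: {0: 0.5} for n in s.nominal_names},
                        np.eye(13))
        GeneratorModel(s, {0: 1.0}, {0: cm})
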