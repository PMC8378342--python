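import numpy as np
import pandas as pd
import pytest

from esdm.evaluation import auc, optimal_threshold
from esdm.sdm_core import (
    ALGORITHMS,
    FitError,
    LearnerSpec,
    TrainingTable,
    balanced_weights,
    fit,
    make_splits,
    make_training_table,
    sre_fit,
    sre_predict,
)

from conftest import LIGHT_HYPERPARAMETERS, make_separable_table


class TestSREnvelope:
    def test_quantile_zero_gives_minmax(self):
        df = pd.DataFrame({"x": [3.0, 1.0, 2.0], "y": [0.0, 5.0, 2.5]})
        env = sre_fit(df, quantile=0.0)
        assert env.lower == {"x": 1.0, "y": 0.0}
        assert env.upper == {"x": 3.0, "y": 5.0}

    def test_constant_predictor_degenerate_bounds(self):
        df = pd.DataFrame({"x": [2.0, 2.0, 2.0]})
        env = sre_fit(df, quantile=0.1)
        assert env.lower["x"] == env.upper["x"] == 2.0

    def test_bounds_match_sort_and_interpolate_oracle(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(size=100)
        env = sre_fit(pd.DataFrame({"x": v}), quantile=0.025)
        s = np.sort(v)
        # manual linear-interpolation order statistic at h = q*(n-1)
        h = 0.025 * 99
        lo = s[int(h)] + (h - int(h)) * (s[int(h) + 1] - s[int(h)])
        h = 0.975 * 99
        hi = s[int(h)] + (h - int(h)) * (s[int(h) + 1] - s[int(h)])
        assert env.lower["x"] == pytest.approx(lo)
        assert env.upper["x"] == pytest.approx(hi)

    def test_quantile_validation(self):
        df = pd.DataFrame({"x": [1.0, 2.0]})
        with pytest.raises(ValueError):
            sre_fit(df, quantile=0.5)
        with pytest.raises(ValueError):
            sre_fit(df.iloc[:1], quantile=0.1)

    def test_predict_centroid_inside_and_outlier_outside(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"x": rng.normal(size=50), "y": rng.normal(size=50)})
        env = sre_fit(df, quantile=0.025)
        centroid = pd.DataFrame({"x": [df["x"].mean()], "y": [df["y"].mean()]})
        assert sre_predict(env, centroid)[0] == 1.0
        above = pd.DataFrame({"x": [env.upper["x"] + 1.0], "y": [df["y"].mean()]})
        assert sre_predict(env, above)[0] == 0.0

    def test_predict_matches_elementwise_interval_oracle(self):
        rng = np.random.default_rng(2)
        train = pd.DataFrame({c: rng.normal(size=60) for c in "abc"})
        env = sre_fit(train, quantile=0.05)
        query = pd.DataFrame({c: rng.normal(size=1000, scale=2) for c in "abc"})
        got = sre_predict(env, query)
        for i in range(len(query)):
            expect = all(
                env.lower[c] <= query[c].iloc[i] <= env.upper[c] for c in "abc"
            )
            assert got[i] == float(expect)

    def test_missing_predictor_named_in_error(self):
        env = sre_fit(pd.DataFrame({"x": [1.0, 2.0], "y": [1.0, 2.0]}))
        with pytest.raises(ValueError, match="y"):
            sre_predict(env, pd.DataFrame({"x": [1.0]}))

    def test_minmax_envelope_monotone_transform_invariant(self):
        rng = np.random.default_rng(3)
        train = pd.DataFrame({"x": rng.uniform(1, 2, 30)})
        query = pd.DataFrame({"x": rng.uniform(0.5, 2.5, 200)})
        base = sre_predict(sre_fit(train, 0.0), query)
        transformed = sre_predict(
            sre_fit(np.exp(train), 0.0), np.exp(query)
        )
        assert np.array_equal(base, transformed)


class TestFit:
    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_separable_table_reaches_training_tss_one(self, algorithm, separable_table):
        spec = LearnerSpec(algorithm, LIGHT_HYPERPARAMETERS.get(algorithm, {}), seed=0)
        model = fit(spec, separable_table)
        scores = model.predict(separable_table.X)
        _, tss_val = optimal_threshold(scores, separable_table.y)
        assert tss_val == pytest.approx(1.0)

    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_predictions_in_unit_interval_and_deterministic(self, algorithm, separable_table):
        spec = LearnerSpec(algorithm, LIGHT_HYPERPARAMETERS.get(algorithm, {}), seed=5)
        model = fit(spec, separable_table)
        rng = np.random.default_rng(9)
        X = pd.DataFrame({"a": rng.normal(0, 5, 300), "b": rng.normal(0, 5, 300)})
        p1, p2 = model.predict(X), model.predict(X)
        assert np.all((p1 >= 0) & (p1 <= 1))
        assert np.array_equal(p1, p2)
        refit = fit(spec, separable_table)
        assert np.array_equal(refit.predict(X), p1)

    def test_no_signal_gives_chance_level_auc(self):
        rng = np.random.default_rng(11)
        n = 400
        data = pd.DataFrame(
            {
                "a": rng.normal(size=n),
                "b": rng.normal(size=n),
                "response": rng.permutation(np.repeat([0, 1], n // 2)),
            }
        )
        data["weight"] = balanced_weights(data["response"].to_numpy())
        table = TrainingTable(data=data, predictors=["a", "b"])
        splits = make_splits(table, k=5, repetitions=2, seed=1)
        aucs = []
        for rep, folds in splits.items():
            for f in range(5):
                model = fit(LearnerSpec("GLM", seed=0), table, rows=np.nonzero(folds != f)[0])
                test = np.nonzero(folds == f)[0]
                aucs.append(auc(model.predict(table.data.iloc[test][table.predictors]), table.y[test]))
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_single_class_subset_raises_fit_error(self, separable_table):
        ones = np.nonzero(separable_table.y == 1)[0]
        with pytest.raises(FitError, match="GLM"):
            fit(LearnerSpec("GLM"), separable_table, rows=ones)

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError):
            LearnerSpec("SVM")

    def test_sre_presence_coverage_on_virtual_species(self, small_stack, small_species):
        # each margin keeps >=95% of presences by construction; jointly at
        # least the Bonferroni bound 1 - 6*0.05 = 70% must be inside
        presences, _ = small_species
        rows, cols = small_stack.grid.cell_of(presences.lon, presences.lat)
        Xp = small_stack.extract(rows, cols)
        env = sre_fit(Xp, quantile=0.025)
        for name in Xp.columns:
            inside = (Xp[name] >= env.lower[name]) & (Xp[name] <= env.upper[name])
            assert inside.mean() >= 0.95 - 1e-9
        assert sre_predict(env, Xp).mean() >= 0.70

    def test_ann_internal_size_selection(self):
        table = make_separable_table(n_per_class=40, seed=3)
        model = fit(LearnerSpec("ANN", {"size": None, "max_iter": 200}, seed=0), table)
        assert model.spec.hyperparameters["size"] in (2, 4, 6, 8)


class TestMakeSplits:
    def _table(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        y = np.repeat([0, 1], n // 2)
        data = pd.DataFrame({"a": rng.normal(size=n), "response": y})
        data["weight"] = balanced_weights(y)
        return TrainingTable(data=data, predictors=["a"])

    def test_fold_sizes_disjoint_union(self):
        table = self._table(100)
        splits = make_splits(table, k=5, repetitions=3, seed=0)
        for folds in splits.values():
            counts = np.bincount(folds, minlength=5)
            assert np.all(counts == 20)

    def test_each_row_tested_once_per_repetition(self):
        table = self._table(60)
        splits = make_splits(table, k=5, repetitions=2, seed=0)
        for folds in splits.values():
            assert set(folds) == set(range(5))

    def test_repetitions_differ(self):
        table = self._table(100)
        splits = make_splits(table, k=5, repetitions=2, seed=0)
        assert not np.array_equal(splits[0], splits[1])

    def test_stratification_within_one_member(self):
        rng = np.random.default_rng(4)
        n = 105  # deliberately not divisible by k
        y = (rng.uniform(size=n) < 0.3).astype(int)
        data = pd.DataFrame({"a": rng.normal(size=n), "response": y})
        data["weight"] = balanced_weights(y)
        table = TrainingTable(data=data, predictors=["a"])
        splits = make_splits(table, k=5, repetitions=2, seed=1)
        n1 = y.sum()
        for folds in splits.values():
            for f in range(5):
                in_fold = folds == f
                expected = n1 * in_fold.sum() / n
                assert abs(y[in_fold].sum() - expected) <= 1.0

    def test_small_class_rejected(self):
        rng = np.random.default_rng(5)
        y = np.array([1, 1, 1] + [0] * 20)
        data = pd.DataFrame({"a": rng.normal(size=23), "response": y})
        data["weight"] = balanced_weights(y)
        table = TrainingTable(data=data, predictors=["a"])
        with pytest.raises(ValueError):
            make_splits(table, k=5)


class TestTrainingTable:
    def test_balanced_weights_equalize_classes(self):
        y = np.array([1] * 10 + [0] * 90)
        w = balanced_weights(y)
        assert w[y == 1].sum() == pytest.approx(w[y == 0].sum())
        assert w.mean() == pytest.approx(1.0)

    def test_make_training_table_from_stack(self, small_stack, small_species):
        from esdm.occurrence import generate_pseudo_absences

        presences, _ = small_species
        bg = generate_pseudo_absences(small_stack, presences, n=100, seed=0)
        table = make_training_table(small_stack, presences, bg)
        assert set(table.predictors) == set(small_stack.names)
        assert (table.y == 1).sum() == len(presences)
        assert (table.y == 0).sum() == 100
        assert not table.X.isna().any().any()

    def test_validation(self):
        data = pd.DataFrame({"a": [1.0, 2.0], "response": [1, 1], "weight": [1.0, 1.0]})
        with pytest.raises(ValueError, match="both classes"):
            TrainingTable(data=data, predictors=["a"])
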