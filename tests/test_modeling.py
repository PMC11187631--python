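import numpy as np
import pytest

import hergsuite as hs
from oracles import confusion_metrics, regression_metrics


class TestStratifiedSplit:
    def test_exact_stratification_arithmetic(self):
        y = np.array(["a"] * 60 + ["b"] * 40)
        train, test = hs.stratified_split(y, test_fraction=0.2, seed=42)
        assert len(test) == 20
        assert np.sum(y[test] == "a") == 12 and np.sum(y[test] == "b") == 8
        assert sorted(np.concatenate([train, test])) == list(range(100))

    def test_determinism_and_seed_sensitivity(self):
        y = np.array(["a", "b"] * 50)
        s1 = hs.stratified_split(y, seed=42)
        s2 = hs.stratified_split(y, seed=42)
        s3 = hs.stratified_split(y, seed=43)
        assert np.array_equal(s1[1], s2[1])
        assert not np.array_equal(s1[1], s3[1])

    def test_regression_binned_stratification(self):
        rng = np.random.RandomState(0)
        y = rng.normal(5, 1, 100)
        train, test = hs.stratified_split(y, task="regression", seed=42)
        assert len(test) == 20
        # binned stratification keeps the test mean close to the global mean
        assert abs(y[test].mean() - y.mean()) < 0.4

    def test_singleton_class_rejected(self):
        with pytest.raises(ValueError):
            hs.stratified_split(np.array(["a"] * 9 + ["b"]))


class TestMetricOracles:
    def test_printed_confusion_example(self):
        # TP=45 FN=5 TN=40 FP=10
        y_true = ["blocker"] * 50 + ["nonblocker"] * 50
        y_pred = ["blocker"] * 45 + ["nonblocker"] * 5 + \
                 ["blocker"] * 10 + ["nonblocker"] * 40
        m = hs.evaluate_classification(y_true, y_pred)
        assert m["se"] == pytest.approx(0.9)
        assert m["sp"] == pytest.approx(0.8)
        assert m["bacc"] == pytest.approx(0.85)
        assert m["mcc"] == pytest.approx(0.7035, abs=1e-4)

    def test_perfect_and_chance_level(self):
        y = ["blocker", "nonblocker"] * 10
        perfect = hs.evaluate_classification(y, y)
        assert perfect["bacc"] == 1.0 and perfect["mcc"] == 1.0
        allsame = hs.evaluate_classification(y, ["blocker"] * 20)
        assert allsame["bacc"] == pytest.approx(0.5)
        assert allsame["mcc"] == 0.0

    def test_binary_metrics_match_bruteforce_on_random_vectors(self):
        rng = np.random.RandomState(7)
        labels = np.array(["blocker", "nonblocker"])
        for _ in range(300):
            y_true = labels[rng.randint(2, size=40)]
            y_pred = labels[rng.randint(2, size=40)]
            if len(set(y_true)) < 2:
                continue
            got = hs.evaluate_classification(y_true, y_pred)
            want = confusion_metrics(y_true, y_pred, positive="blocker")
            for key, val in want.items():
                assert got[key] == pytest.approx(val, abs=1e-9), key

    def test_regression_metrics_match_bruteforce(self):
        rng = np.random.RandomState(11)
        for _ in range(300):
            y_true = rng.normal(5, 1, 30)
            y_pred = y_true + rng.normal(0, 0.5, 30)
            got = hs.evaluate_regression(y_true, y_pred)
            want = regression_metrics(y_true, y_pred)
            for key, val in want.items():
                assert got[key] == pytest.approx(val, abs=1e-9), key
            assert got["rmse"] ** 2 == pytest.approx(got["mse"], abs=1e-12)

    def test_auc_uses_positive_class_column(self):
        y = ["blocker"] * 3 + ["nonblocker"] * 3
        # probability matrix in sorted class order: blocker column first
        proba = np.array([[0.9, 0.1]] * 3 + [[0.2, 0.8]] * 3)
        m = hs.evaluate_classification(y, y, scores=proba)
        assert m["auc"] == pytest.approx(1.0)

    def test_printed_regression_example(self):
        m = hs.evaluate_regression([1, 2, 3], [1, 2, 4])
        assert m["mse"] == pytest.approx(1 / 3)
        assert m["mae"] == pytest.approx(1 / 3)
        assert m["rmse"] == pytest.approx(0.5774, abs=1e-4)
        assert m["r2"] == pytest.approx(0.5)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            hs.evaluate_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            hs.evaluate_classification(["a"], ["a", "b"])


class TestTraining:
    def test_planted_signal_recovery(self, trained_binary, fps_binary):
        bundle, train_idx, test_idx, y = trained_binary
        m = hs.evaluate_classification(
            y[test_idx], bundle.predict(fps_binary.bits[test_idx]))
        assert m["bacc"] >= 0.85

    def test_degenerate_targets_rejected(self):
        X = np.random.RandomState(0).randint(0, 2, (20, 8))
        spec = hs.ModelSpec(task="binary", algorithm="random_forest")
        with pytest.raises(ValueError):
            hs.train_model(spec, X, ["blocker"] * 20)
        spec_r = hs.ModelSpec(task="regression", algorithm="random_forest")
        with pytest.raises(ValueError):
            hs.train_model(spec_r, X, np.ones(20))

    def test_serialization_round_trip(self, tmp_path, trained_binary, fps_binary):
        bundle, train_idx, test_idx, y = trained_binary
        bundle.save(tmp_path / "m")
        reloaded = hs.TrainedModelBundle.load(tmp_path / "m")
        X = fps_binary.bits[test_idx]
        assert np.array_equal(reloaded.predict(X), bundle.predict(X))
        assert reloaded.spec == bundle.spec

    def test_forest_ranks_planted_bits_top_decile(self, planted, curated_binary,
                                                  fps_binary):
        _, truth, _ = planted
        y = np.array(curated_binary.labels)
        spec = hs.ModelSpec(task="binary", algorithm="random_forest",
                            hyperparameters={"n_estimators": 100})
        bundle = hs.train_model(spec, fps_binary.bits, y)
        importances = bundle.model.feature_importances_
        cutoff = np.quantile(importances, 0.9)
        for bit in truth["signal_bits"]:
            assert importances[bit] >= cutoff


class TestCrossValidation:
    def test_fold_partition_and_determinism(self, curated_binary, fps_binary):
        y = np.array(curated_binary.labels)
        spec = hs.ModelSpec(task="binary", algorithm="knn")
        r1 = hs.cross_validate(spec, fps_binary, y, folds=5, seed=1)
        r2 = hs.cross_validate(spec, fps_binary, y, folds=5, seed=1)
        assert r1.metrics == r2.metrics
        assert 0.0 <= r1["bacc"] <= 1.0 and "bacc" in r1.stds

    def test_too_many_folds(self):
        X = np.random.RandomState(0).randint(0, 2, (6, 4))
        y = ["a", "a", "a", "a", "b", "b"]
        spec = hs.ModelSpec(task="binary", algorithm="knn",
                            hyperparameters={"n_neighbors": 1})
        with pytest.raises(ValueError):
            hs.cross_validate(spec, X, y, folds=3)


class TestYRandomization:
    def test_scrambled_performance_is_chance_level(self, trained_binary,
                                                   fps_binary):
        bundle, train_idx, test_idx, y = trained_binary
        spec = bundle.spec
        reports = hs.y_randomization(
            spec, fps_binary.bits[train_idx], y[train_idx],
            fps_binary.bits[test_idx], y[test_idx], rounds=20, seed=42)
        assert len(reports) == 20
        scrambled = np.array([r["bacc"] for r in reports])
        assert 0.4 <= scrambled.mean() <= 0.6
        real = hs.evaluate_classification(
            y[test_idx], bundle.predict(fps_binary.bits[test_idx]))["bacc"]
        assert real - scrambled.mean() >= 0.2

    def test_single_round_reproducible(self, trained_binary, fps_binary):
        bundle, train_idx, test_idx, y = trained_binary
        kw = dict(rounds=1, seed=7)
        r1 = hs.y_randomization(bundle.spec, fps_binary.bits[train_idx],
                                y[train_idx], fps_binary.bits[test_idx],
                                y[test_idx], **kw)
        r2 = hs.y_randomization(bundle.spec, fps_binary.bits[train_idx],
                                y[train_idx], fps_binary.bits[test_idx],
                                y[test_idx], **kw)
        assert r1[0].metrics == r2[0].metrics


class TestTuning:
    def _data(self):
        rng = np.random.RandomState(0)
        X = rng.randint(0, 2, (60, 16)).astype(float)
        y = np.where(X[:, 3] > 0, "blocker", "nonblocker")
        return X, y

    def test_budget_one_returns_single_trial(self):
        X, y = self._data()
        spec = hs.ModelSpec(task="binary", algorithm="knn")
        best, log = hs.tune_hyperparameters(spec, X, y, budget=1, folds=3, seed=0)
        assert len(log) == 1
        assert best.hyperparameters == log[0].hyperparameters

    def test_best_is_max_of_trial_log_and_deterministic(self):
        X, y = self._data()
        spec = hs.ModelSpec(task="binary", algorithm="knn")
        best1, log1 = hs.tune_hyperparameters(spec, X, y, budget=6, folds=3, seed=5)
        best2, log2 = hs.tune_hyperparameters(spec, X, y, budget=6, folds=3, seed=5)
        assert [t.hyperparameters for t in log1] == [t.hyperparameters for t in log2]
        assert max(t.score for t in log1) == pytest.approx(
            next(t.score for t in log1 if t.hyperparameters == best1.hyperparameters))

    def test_empty_space_rejected(self):
        X, y = self._data()
        spec = hs.ModelSpec(task="binary", algorithm="knn")
        with pytest.raises(ValueError):
            hs.tune_hyperparameters(spec, X, y, search_space={}, budget=2)
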