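import numpy as np
import pytest

from loopanchor.features import design_matrix
from loopanchor.metrics import auroc
from loopanchor.models import (
    MODEL_NAMES,
    ModelSpec,
    cross_validate,
    fit_arrays,
    make_split,
    train,
)

from conftest import random_feature_rows


class TestMakeSplit:
    def test_sizes_for_n100_k10(self):
        labels = np.tile([0, 1], 50)
        plan = make_split(100, labels, k=10, test_fraction=0.1, seed=0)
        assert plan.test_indices.size == 10
        assert plan.train_indices.size == 90
        assert all(f.size == 9 for f in plan.folds)

    def test_same_seed_is_identical(self):
        labels = np.tile([0, 1], 50)
        p1 = make_split(100, labels, seed=5)
        p2 = make_split(100, labels, seed=5)
        assert np.array_equal(p1.test_indices, p2.test_indices)
        assert all(np.array_equal(a, b) for a, b in zip(p1.folds, p2.folds))

    def test_set_algebra_on_random_configurations(self):
        rng = np.random.default_rng(1)
        for trial in range(50):
            n = int(rng.integers(60, 400))
            frac_pos = rng.uniform(0.3, 0.7)
            labels = (rng.random(n) < frac_pos).astype(int)
            if labels.sum() < 12 or (1 - labels).sum() < 12:
                continue
            k = int(rng.integers(2, 8))
            plan = make_split(n, labels, k=k, test_fraction=0.1,
                              seed=int(rng.integers(0, 1000)))
            test, trainset = set(plan.test_indices), set(plan.train_indices)
            assert test | trainset == set(range(n))
            assert not (test & trainset)
            fold_union = set()
            for f in plan.folds:
                fset = set(f.tolist())
                assert not (fold_union & fset)
                fold_union |= fset
            assert fold_union == trainset
            assert max(f.size for f in plan.folds) - min(
                f.size for f in plan.folds) <= 1
            # stratification: train ratio near the global label ratio
            global_ratio = labels.mean()
            train_ratio = labels[plan.train_indices].mean()
            assert abs(train_ratio - global_ratio) <= 0.02 + 1.0 / plan.train_indices.size

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            make_split(100, np.ones(100), k=10)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            make_split(10, np.tile([0, 1], 5), k=10)


def separable_toy(n=60, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(0, 0.3, size=(n, 2)) + y[:, None] * 4.0
    return X, y


class TestTrain:
    def test_svm_separates_toy_data(self):
        X, y = separable_toy()
        model = fit_arrays(ModelSpec("SVM"), X, y, continuous_cols=(0, 1))
        scores = model.predict_scores(X)
        assert ((scores >= 0.5).astype(int) == y).all()

    def test_rf_deterministic_per_seed(self):
        rows = random_feature_rows(120, effect=1.0, seed=2)
        s1 = train(ModelSpec("RF", {"n_estimators": 50}, seed=9), rows)
        s2 = train(ModelSpec("RF", {"n_estimators": 50}, seed=9), rows)
        X, _ = design_matrix(rows)
        assert np.array_equal(s1.predict_scores(X), s2.predict_scores(X))

    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_every_model_trains_on_synthetic_matrix(self, name):
        rows = random_feature_rows(200, effect=1.5, seed=3)
        hp = {"n_estimators": 50} if name == "RF" else \
             {"epochs": 30} if name == "CNN" else {}
        model = train(ModelSpec(name, hp, seed=1), rows)
        X, y = design_matrix(rows)
        scores = model.predict_scores(X)
        assert scores.shape == (200,)
        assert (scores >= 0.0).all() and (scores <= 1.0).all()
        # the intensity signal is strong: training AUROC clearly above chance
        assert auroc(y, scores) > 0.6

    def test_unsupported_name_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("GBM")

    def test_dimension_mismatch_rejected(self):
        rows = random_feature_rows(60, seed=4)
        model = train(ModelSpec("LR"), rows)
        with pytest.raises(ValueError):
            model.predict_scores(np.zeros((3, 10)))

    def test_planted_signal_orders_scores(self):
        rows = random_feature_rows(200, effect=3.0, seed=5)
        model = train(ModelSpec("LR"), rows)
        X, y = design_matrix(rows)
        scores = model.predict_scores(X)
        assert scores[y == 1].mean() > scores[y == 0].mean()


class TestCrossValidate:
    def test_cardinality(self):
        rows = random_feature_rows(150, effect=1.0, seed=6)
        plan = make_split(150, [r.label for r in rows], k=10, seed=0)
        res = cross_validate(ModelSpec("LR"), rows, plan)
        assert len(res.fold_reports) == 10
        assert res.test_report is not None

    def test_shuffled_labels_give_chance_auroc(self):
        rng = np.random.default_rng(7)
        rows = random_feature_rows(2000, effect=2.0, seed=7)
        labels = np.array([r.label for r in rows])
        shuffled = rng.permutation(labels)
        X, _ = design_matrix(rows)
        plan = make_split(2000, shuffled, k=10, seed=1)
        res = cross_validate(ModelSpec("LR", seed=1), (X, shuffled), plan)
        assert 0.4 <= res.test_report.auroc <= 0.6

    def test_fold_models_never_see_test_rows(self):
        rows = random_feature_rows(200, effect=1.0, seed=8)
        labels = [r.label for r in rows]
        plan = make_split(200, labels, k=5, seed=2)
        X, y = design_matrix(rows)
        res_full = cross_validate(ModelSpec("LR", seed=2), (X, y), plan)
        # corrupt the held-out rows: fold reports must be bit-identical
        X2 = X.copy()
        X2[plan.test_indices] = 0.0
        res_corrupt = cross_validate(ModelSpec("LR", seed=2), (X2, y), plan)
        assert res_full.fold_reports == res_corrupt.fold_reports

    def test_end_to_end_determinism(self):
        rows = random_feature_rows(150, effect=1.0, seed=9)
        plan = make_split(150, [r.label for r in rows], k=5, seed=3)
        for name in ("SVM", "RF", "LR", "LDA", "NB", "SGD"):
            hp = {"n_estimators": 30} if name == "RF" else {}
            r1 = cross_validate(ModelSpec(name, hp, seed=4), rows, plan)
            r2 = cross_validate(ModelSpec(name, hp, seed=4), rows, plan)
            assert r1.test_report == r2.test_report
            assert r1.fold_reports == r2.fold_reports
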