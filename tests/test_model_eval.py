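import numpy as np
import pandas as pd
import pytest
from sklearn.base import BaseEstimator, ClassifierMixin

from methylsubtypes.balancing import SmoteConfig, balance
from methylsubtypes.datasets import SimulationConfig, generate_dataset
from methylsubtypes.io import BetaMatrix
from methylsubtypes.model_eval import (
    ClassifierSpec,
    PolyOvrSVM,
    confusion_metrics,
    cross_validate,
    ifs,
    multiclass_mcc,
    train_predict_rf,
)
from methylsubtypes.relevance import mr_filter


def binary_mcc_formula(table):
    """Classical 2×2 MCC oracle: (ad − bc)/√((a+b)(c+d)(a+c)(b+d))."""
    (a, b), (c, d) = np.asarray(table, dtype=float)
    denom = np.sqrt((a + b) * (c + d) * (a + c) * (b + d))
    return 0.0 if denom == 0 else (a * d - b * c) / denom


def blobs_matrix(n_per_class=30, spread=0.03, seed=0):
    """Four well-separated Gaussian blobs squeezed into [0, 1]^2."""
    rng = np.random.default_rng(seed)
    centers = np.array([[0.2, 0.2], [0.2, 0.8], [0.8, 0.2], [0.8, 0.8]])
    values, labels = [], []
    for i, c in enumerate(centers):
        values.append(np.clip(rng.normal(c, spread, size=(n_per_class, 2)), 0, 1))
        labels += [f"class{i}"] * n_per_class
    values = np.vstack(values)
    return BetaMatrix(
        values,
        [f"s{i}" for i in range(len(labels))],
        ["p0", "p1"],
        np.array(labels, dtype=object),
    )


class _LabelReader(ClassifierMixin, BaseEstimator):
    """Oracle stub: reads the class straight out of feature 0."""

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        return self

    def predict(self, X):
        return np.asarray([f"class{int(round(v * 10))}" for v in X[:, 0]], dtype=object)


class _SpecStub(ClassifierSpec):
    def build(self):
        return _LabelReader()


class TestPolyOvrSVM:
    def test_separable_two_class_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-2, 0.3, (20, 2)), rng.normal(2, 0.3, (20, 2))])
        y = np.array(["neg"] * 20 + ["pos"] * 20)
        clf = PolyOvrSVM(degree=1).fit(X, y)
        assert (clf.predict(X) == y).all()

    def test_tied_scores_break_to_majority_class(self):
        clf = PolyOvrSVM()
        clf.classes_ = np.array(["a", "b", "c"])
        clf.class_counts_ = np.array([5, 9, 5])
        clf.decision_function = lambda X: np.zeros((len(X), 3))
        assert list(clf.predict(np.zeros((2, 4)))) == ["b", "b"]

    def test_tied_scores_and_counts_break_lexicographic(self):
        clf = PolyOvrSVM()
        clf.classes_ = np.array(["c", "a", "b"])
        clf.class_counts_ = np.array([5, 5, 5])
        clf.decision_function = lambda X: np.zeros((len(X), 3))
        assert list(clf.predict(np.zeros((1, 4)))) == ["a"]

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            PolyOvrSVM().fit(np.zeros((5, 2)), np.repeat("a", 5))

    def test_separated_blobs_cross_validate_above_095(self):
        matrix = blobs_matrix()
        conf, y_pred = cross_validate(matrix, ClassifierSpec("svm_ovr", seed=1), folds=10, seed=1)
        assert multiclass_mcc(y_pred.astype(str), matrix.labels.astype(str)) > 0.95

    def test_probability_mode_predicts_blobs(self):
        matrix = blobs_matrix(n_per_class=20)
        spec = ClassifierSpec("svm_ovr", score_mode="probability", seed=2)
        clf = spec.build().fit(matrix.values, matrix.labels.astype(str))
        assert (clf.predict(matrix.values) == matrix.labels).mean() > 0.95


class TestRandomForest:
    def test_separated_blobs_cross_validate_above_095(self):
        matrix = blobs_matrix(seed=3)
        conf, y_pred = cross_validate(
            matrix, ClassifierSpec("random_forest", n_trees=50, seed=4), folds=10, seed=4
        )
        assert multiclass_mcc(y_pred.astype(str), matrix.labels.astype(str)) > 0.95

    def test_train_predict_round_trip(self):
        matrix = blobs_matrix(seed=5)
        preds = train_predict_rf(matrix, matrix.values[:5], ClassifierSpec("random_forest", n_trees=20, seed=6))
        assert len(preds) == 5


class TestCrossValidate:
    def test_confusion_rows_sum_to_class_sizes(self):
        matrix = blobs_matrix(n_per_class=25, seed=7)
        conf, _ = cross_validate(matrix, ClassifierSpec("svm_ovr", seed=8), folds=5, seed=8)
        assert conf.sum(axis=1).tolist() == [25, 25, 25, 25]

    def test_same_seed_identical_folds_and_confusion(self):
        matrix = blobs_matrix(n_per_class=20, spread=0.25, seed=9)
        a, _ = cross_validate(matrix, ClassifierSpec("svm_ovr", seed=10), folds=5, seed=10)
        b, _ = cross_validate(matrix, ClassifierSpec("svm_ovr", seed=10), folds=5, seed=10)
        pd.testing.assert_frame_equal(a, b)

    def test_label_memorizing_oracle_gives_identity_confusion(self):
        # feature 0 encodes the class, so the stub is exact on unseen folds
        rng = np.random.default_rng(11)
        labels = np.repeat([f"class{i}" for i in range(3)], 12)
        values = np.column_stack(
            [np.repeat([0.0, 0.1, 0.2], 12), rng.uniform(size=36)]
        )
        matrix = BetaMatrix(values, [f"s{i}" for i in range(36)], ["p0", "p1"], labels.astype(object))
        conf, _ = cross_validate(matrix, _SpecStub(), folds=3, seed=0)
        assert np.array_equal(np.diag(conf.to_numpy()), [12, 12, 12])

    def test_class_smaller_than_fold_count_rejected(self):
        matrix = blobs_matrix(n_per_class=5)
        with pytest.raises(ValueError, match="folds"):
            cross_validate(matrix, ClassifierSpec(), folds=10, seed=0)


class TestConfusionMetrics:
    def test_identity_confusion_all_ones(self):
        metrics = confusion_metrics(np.diag([5, 7, 9]))
        assert all(v == 1.0 for v in metrics["sensitivity"].values())
        assert all(v == 1.0 for v in metrics["specificity"].values())
        assert metrics["accuracy"] == 1.0

    def test_two_by_two_hand_values(self):
        metrics = confusion_metrics(np.array([[8, 2], [1, 9]]))
        assert metrics["sensitivity"]["0"] == pytest.approx(0.8)
        assert metrics["sensitivity"]["1"] == pytest.approx(0.9)
        assert metrics["specificity"]["0"] == pytest.approx(0.9)
        assert metrics["specificity"]["1"] == pytest.approx(0.8)
        assert metrics["accuracy"] == pytest.approx(0.85)

    def test_accuracy_is_size_weighted_mean_sensitivity(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            conf = rng.integers(0, 30, size=(4, 4)).astype(float)
            conf += np.diag(rng.integers(1, 10, size=4))
            m = confusion_metrics(conf)
            n_c = conf.sum(axis=1)
            weighted = sum(
                m["sensitivity"][str(i)] * n_c[i] for i in range(4)
            ) / n_c.sum()
            assert m["accuracy"] == pytest.approx(weighted, abs=1e-12)


class TestMulticlassMcc:
    def test_perfect_agreement_is_one(self):
        y = np.repeat(["a", "b", "c"], 10)
        assert multiclass_mcc(y, y) == pytest.approx(1.0)

    def test_constant_prediction_is_zero_by_convention(self):
        y_true = np.array(["a", "b", "a", "b"])
        assert multiclass_mcc(np.repeat("a", 4), y_true) == 0.0

    def test_binary_case_reduces_to_classical_formula(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            table = rng.integers(0, 12, size=(2, 2))
            if table.sum() == 0:
                continue
            y_true, y_pred = [], []
            for i in range(2):
                for j in range(2):
                    y_true += [i] * table[i, j]
                    y_pred += [j] * table[i, j]
            got = multiclass_mcc(np.array(y_pred), np.array(y_true))
            assert got == pytest.approx(binary_mcc_formula(table), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            multiclass_mcc(["a"], ["a", "b"])


class TestIfs:
    def test_single_subset_list_is_its_own_optimum(self):
        matrix = blobs_matrix(n_per_class=20, seed=14)
        result = ifs(["p0", "p1"], matrix, ClassifierSpec(seed=15), step=10, folds=5, seed=15)
        assert len(result.evaluations) == 1
        assert result.optimum_k == 2

    def test_final_partial_subset_included(self, small_cohort):
        matrix, _ = small_cohort
        ranked = matrix.probe_ids[:25]
        result = ifs(ranked, matrix, _SpecStub(), step=10, folds=5, seed=0)
        assert [ev.k for ev in result.evaluations] == [10, 20, 25]

    def test_equal_mcc_ties_resolve_to_smaller_k(self):
        # the stub predicts from feature 0 regardless of the subset, so every
        # k yields the same MCC and the tie rule must pick the smallest
        rng = np.random.default_rng(16)
        labels = np.repeat([f"class{i}" for i in range(3)], 15)
        values = np.column_stack(
            [np.repeat([0.0, 0.1, 0.2], 15)] + [rng.uniform(size=45) for _ in range(30)]
        )
        matrix = BetaMatrix(
            values, [f"s{i}" for i in range(45)],
            [f"p{i}" for i in range(31)], labels.astype(object),
        )
        result = ifs(matrix.probe_ids, matrix, _SpecStub(), step=10, folds=3, seed=0)
        mccs = {ev.mcc for ev in result.evaluations}
        assert len(mccs) == 1
        assert result.optimum_k == 10

    def test_empty_ranking_rejected(self, small_cohort):
        matrix, _ = small_cohort
        with pytest.raises(ValueError, match="empty"):
            ifs([], matrix, ClassifierSpec())


def test_luminal_classes_are_the_hard_ones_under_proximity():
    """With the lumA↔lumB proximity flag on, the class with the lowest CV
    sensitivity is one of the two luminal-like classes."""
    matrix, _ = generate_dataset(
        SimulationConfig(n_probes=150, n_informative=15, effect=0.35,
                         lum_proximity=True, seed=7)
    )
    retained = mr_filter(matrix, threshold=0.1).retained[:20]
    balanced = balance(matrix.subset_probes(retained), SmoteConfig(k=5, seed=8))
    conf, _ = cross_validate(balanced, ClassifierSpec("svm_ovr", seed=9), folds=10, seed=9)
    sens = confusion_metrics(conf)["sensitivity"]
    assert min(sens, key=sens.get) in {"lumA", "lumB"}
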