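"""Classifier evaluation: one-vs-rest polynomial SVM, random forest,
stratified 10-fold cross-validation, multi-class MCC, and incremental
feature selection (IFS).

The multi-class Matthews correlation coefficient is computed as the
correlation between the binary indicator matrices X (predicted) and Y
(true):

    MCC = cov(X, Y) / sqrt(cov(X, X) · cov(Y, Y))

with all covariances summed over the column-centered entries.  IFS sweeps
nested top-k prefixes of a ranked feature list (step 10 by default),
cross-validates a classifier on each, and keeps the prefix with maximal MCC
(ties broken toward the smaller k).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, check_X_y

from .io import BetaMatrix

__all__ = [
    "ClassifierSpec",
    "PolyOvrSVM",
    "FeatureSubsetEvaluation",
    "IfsResult",
    "train_predict_ovr_svm",
    "train_predict_rf",
    "cross_validate",
    "confusion_metrics",
    "multiclass_mcc",
    "ifs",
]


@dataclass
class ClassifierSpec:
    """Which classifier to evaluate and with what hyperparameters.

    family "svm_ovr": one-vs-rest SVM with polynomial kernel (degree, C);
    family "random_forest": bagged trees (n_trees).  ``score_mode`` picks the
    per-class score of the OVR SVM: raw decision values ("decision", default)
    or Platt-calibrated probabilities ("probability").
    """

    family: str = "svm_ovr"
    degree: int = 1
    C: float = 1.0
    n_trees: int = 100
    score_mode: str = "decision"
    seed: int = 0

    def validate(self) -> None:
        if self.family not in ("svm_ovr", "random_forest"):
            raise ValueError(f"unknown classifier family {self.family!r}")
        if self.degree < 1:
            raise ValueError("polynomial degree must be ≥ 1")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.n_trees < 1:
            raise ValueError("tree count must be ≥ 1")
        if self.score_mode not in ("decision", "probability"):
            raise ValueError("score_mode must be 'decision' or 'probability'")

    def build(self):
        self.validate()
        if self.family == "svm_ovr":
            return PolyOvrSVM(
                degree=self.degree,
                C=self.C,
                score_mode=self.score_mode,
                random_state=self.seed,
            )
        return RandomForestClassifier(
            n_estimators=self.n_trees, random_state=self.seed
        )


class PolyOvrSVM(ClassifierMixin, BaseEstimator):
    """One-vs-rest multi-class SVM with a polynomial kernel.

    One binary SVC is trained per class (that class vs the rest); a query
    sample is assigned the class whose binary machine scores it highest.
    Exact score ties are broken toward the class with more training samples,
    then lexicographically.

    Parameters
    ----------
    degree : polynomial kernel degree (1 = linear-in-kernel).
    C : SVM regularization.
    score_mode : "decision" uses signed decision values; "probability" uses
        Platt-calibrated class probabilities.
    random_state : seeds the (stochastic) Platt calibration.
    """

    def __init__(
        self,
        degree: int = 1,
        C: float = 1.0,
        score_mode: str = "decision",
        random_state: int = 0,
    ):
        self.degree = degree
        self.C = C
        self.score_mode = score_mode
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.classes_, counts = np.unique(y, return_counts=True)
        if len(self.classes_) < 2:
            raise ValueError("one-vs-rest SVM needs at least 2 classes")
        self.class_counts_ = counts
        self.estimators_ = []
        for c in self.classes_:
            svc = SVC(
                kernel="poly",
                degree=self.degree,
                C=self.C,
                gamma="scale",
                coef0=1.0,
                random_state=self.random_state,
            )
            if self.score_mode == "probability":
                # Platt sigmoid calibration of the binary margins
                svc = CalibratedClassifierCV(svc, method="sigmoid", ensemble=False)
            svc.fit(X, (y == c).astype(int))
            self.estimators_.append(svc)
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "estimators_")
        X = np.asarray(X, dtype=float)
        cols = []
        for svc in self.estimators_:
            if self.score_mode == "probability":
                pos = list(svc.classes_).index(1)
                cols.append(svc.predict_proba(X)[:, pos])
            else:
                cols.append(svc.decision_function(X))
        return np.column_stack(cols)

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        out = np.empty(scores.shape[0], dtype=object)
        for i, row in enumerate(scores):
            top = row.max()
            tied = np.flatnonzero(row >= top - 1e-12)
            # prefer the majority training class, then lexicographic order
            best = min(
                tied, key=lambda j: (-self.class_counts_[j], str(self.classes_[j]))
            )
            out[i] = self.classes_[best]
        return out


def train_predict_ovr_svm(train: BetaMatrix, test_values, spec: ClassifierSpec):
    """Fit a one-vs-rest polynomial SVM on a labeled matrix, predict rows."""
    clf = ClassifierSpec(
        "svm_ovr", spec.degree, spec.C, spec.n_trees, spec.score_mode, spec.seed
    ).build()
    clf.fit(train.values, train.labels.astype(str))
    return clf.predict(np.asarray(test_values, dtype=float))


def train_predict_rf(train: BetaMatrix, test_values, spec: ClassifierSpec):
    """Fit a random forest on a labeled matrix, predict the given rows."""
    clf = ClassifierSpec(
        "random_forest", spec.degree, spec.C, spec.n_trees, spec.score_mode, spec.seed
    ).build()
    clf.fit(train.values, train.labels.astype(str))
    return clf.predict(np.asarray(test_values, dtype=float))


def _cv_predict(X, y, estimator, folds, seed, balancer=None):
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y_pred = np.empty(len(y), dtype=object)
    for train_idx, test_idx in skf.split(X, y):
        X_tr, y_tr = X[train_idx], y[train_idx]
        if balancer is not None:
            X_tr, y_tr = clone(balancer).fit_resample(X_tr, y_tr)
        model = clone(estimator).fit(X_tr, y_tr)
        y_pred[test_idx] = model.predict(X[test_idx])
    return y_pred


def cross_validate(
    matrix: BetaMatrix,
    spec: ClassifierSpec,
    folds: int = 10,
    seed: int = 0,
    balancer=None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Stratified k-fold CV; every sample is predicted exactly once.

    When ``balancer`` (a fit_resample object) is given, oversampling happens
    inside each training fold only — the leak-free alternative to balancing
    the full dataset up front.

    Returns the accumulated C × C confusion matrix (rows = true class,
    labels sorted) and the per-sample predictions.
    """
    y = matrix.labels.astype(str)
    classes = matrix.classes
    smallest = min(matrix.class_sizes().values())
    if smallest < folds:
        raise ValueError(
            f"smallest class has {smallest} samples, fewer than {folds} folds"
        )
    y_pred = _cv_predict(matrix.values, y, spec.build(), folds, seed, balancer)
    conf = _sk_confusion(y, y_pred.astype(str), labels=classes)
    return pd.DataFrame(conf, index=classes, columns=classes), y_pred


def confusion_metrics(confusion) -> dict:
    """Per-class sensitivity/specificity and overall accuracy.

    sensitivity_c = TP_c / (row sum c); specificity_c = TN_c / (TN_c + FP_c);
    accuracy = trace / total.  Accepts a labeled DataFrame or plain array.
    """
    if isinstance(confusion, pd.DataFrame):
        labels = [str(c) for c in confusion.index]
        conf = confusion.to_numpy(dtype=float)
    else:
        conf = np.asarray(confusion, dtype=float)
        labels = [str(i) for i in range(conf.shape[0])]
    total = conf.sum()
    tp = np.diag(conf)
    row = conf.sum(axis=1)
    col = conf.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(row > 0, tp / row, 0.0)
        tn = total - row - col + tp
        fp = col - tp
        spec = np.where((tn + fp) > 0, tn / (tn + fp), 0.0)
    return {
        "sensitivity": dict(zip(labels, sens)),
        "specificity": dict(zip(labels, spec)),
        "accuracy": float(tp.sum() / total) if total else 0.0,
    }


def multiclass_mcc(y_pred, y_true) -> float:
    """Multi-class Matthews correlation from indicator-matrix covariances.

    Builds the n × C one-hot matrices of predictions and truth over the
    union of observed labels and returns cov(X,Y)/√(cov(X,X)·cov(Y,Y)).
    Degenerate inputs (either matrix with zero column variance everywhere,
    e.g. a constant prediction) return 0 by convention.
    """
    y_pred = np.asarray(y_pred)
    y_true = np.asarray(y_true)
    if len(y_pred) != len(y_true):
        raise ValueError("prediction/truth length mismatch")
    labels = np.unique(np.concatenate([y_pred, y_true]))
    if len(labels) < 2:
        return 0.0
    index = {l: i for i, l in enumerate(labels)}
    n = len(y_true)
    X = np.zeros((n, len(labels)))
    Y = np.zeros((n, len(labels)))
    X[np.arange(n), [index[l] for l in y_pred]] = 1.0
    Y[np.arange(n), [index[l] for l in y_true]] = 1.0
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    cov_xy = float(np.sum(Xc * Yc))
    cov_xx = float(np.sum(Xc * Xc))
    cov_yy = float(np.sum(Yc * Yc))
    if cov_xx == 0.0 or cov_yy == 0.0:
        return 0.0
    return cov_xy / np.sqrt(cov_xx * cov_yy)


@dataclass
class FeatureSubsetEvaluation:
    """Cross-validation result for one top-k feature prefix."""

    k: int
    features: list[str]
    confusion: pd.DataFrame
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    accuracy: float
    mcc: float


@dataclass
class IfsResult:
    """Full IFS sweep: one evaluation per k, plus the max-MCC optimum."""

    evaluations: list[FeatureSubsetEvaluation] = field(default_factory=list)

    @property
    def optimum(self) -> FeatureSubsetEvaluation:
        if not self.evaluations:
            raise ValueError("empty IFS result")
        # max MCC; ties resolved toward the smaller feature count
        return min(self.evaluations, key=lambda ev: (-ev.mcc, ev.k))

    @property
    def optimum_k(self) -> int:
        return self.optimum.k

    @property
    def optimum_features(self) -> list[str]:
        return self.optimum.features

    def to_frame(self) -> pd.DataFrame:
        classes = list(self.evaluations[0].sensitivity) if self.evaluations else []
        rows = []
        for ev in self.evaluations:
            row: dict = {"k": ev.k}
            row.update({f"sensitivity_{c}": ev.sensitivity[c] for c in classes})
            row.update({f"specificity_{c}": ev.specificity[c] for c in classes})
            row["accuracy"] = ev.accuracy
            row["mcc"] = ev.mcc
            rows.append(row)
        return pd.DataFrame(rows)


def ifs(
    ranked: list[str],
    matrix: BetaMatrix,
    spec: ClassifierSpec,
    step: int = 10,
    folds: int = 10,
    seed: int = 0,
    max_k: int | None = None,
    balancer=None,
) -> IfsResult:
    """Incremental feature selection over nested top-k prefixes.

    Evaluates k = step, 2·step, … up to the ranked-list length (a final
    partial prefix is included; ``max_k`` caps the sweep).  Each prefix is
    scored by stratified CV; the optimum is the max-MCC prefix.
    """
    ranked = list(ranked)
    if not ranked:
        raise ValueError("ranked feature list is empty")
    limit = len(ranked) if max_k is None else min(max_k, len(ranked))
    ks = list(range(step, limit + 1, step))
    if not ks or ks[-1] < limit:
        ks.append(limit)
    result = IfsResult()
    for k in ks:
        feats = ranked[:k]
        sub = matrix.subset_probes(feats)
        conf, y_pred = cross_validate(sub, spec, folds=folds, seed=seed, balancer=balancer)
        metrics = confusion_metrics(conf)
        mcc = multiclass_mcc(y_pred.astype(str), sub.labels.astype(str))
        result.evaluations.append(
            FeatureSubsetEvaluation(
                k=k,
                features=feats,
                confusion=conf,
                sensitivity=metrics["sensitivity"],
                specificity=metrics["specificity"],
                accuracy=metrics["accuracy"],
                mcc=mcc,
            )
        )
    return result
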