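"""Stratified splitting, classifier tuning and performance metrics.

The primary classifier is a random forest tuned over ``mtry`` (the number of
features sampled at each split) by grid search under repeated stratified
k-fold cross-validation, with XGBoost, an RBF-kernel SVM and naive Bayes as
pluggable alternatives behind the same interface. Class probabilities are the
fraction of trees voting for a class and feed the applicability-domain gates.

Small classes get special treatment: classes with fewer than
``min_class_size`` labelled members are excluded from modelling (relabelled
"Z"), and classes of 3-5 members are split 50:50 instead of 80:20.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold, cross_val_score
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .chem_io import CompoundSet
from .descriptors import ScalingStats
from .errors import ValidationError

ALGORITHMS = ("rf", "xgboost", "svm", "nb")


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/test split policy.

    Classes with fewer than ``min_class_size`` members are excluded; classes
    with ``min_class_size``..``small_max`` members use ``ratio_small``;
    larger classes use ``ratio_default``. Train counts round half-up, with at
    least one test member per included class.
    """

    ratio_default: float = 0.8
    ratio_small: float = 0.5
    min_class_size: int = 3
    small_max: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.ratio_default < 1 and 0 < self.ratio_small < 1):
            raise ValidationError("split ratios must lie in (0, 1)")
        if self.min_class_size < 1:
            raise ValidationError("min_class_size must be >= 1")


def stratified_split(
    compounds: CompoundSet, label_field: str, spec: SplitSpec = SplitSpec()
) -> tuple[list[str], list[str], list[str]]:
    """Split a labelled compound set into (train ids, test ids, excluded ids).

    Unlabelled records and members of classes smaller than
    ``spec.min_class_size`` go to the excluded list (to be treated as the
    unclassified "Z" pool). The split is deterministic given ``spec.seed``.
    """
    labels = compounds.labels(label_field)
    ids = compounds.ids
    return split_ids_by_class(ids, labels, spec)


def split_ids_by_class(
    ids: Sequence[str], labels: Sequence[str | None], spec: SplitSpec = SplitSpec()
) -> tuple[list[str], list[str], list[str]]:
    if len(ids) != len(labels):
        raise ValidationError("ids and labels must have equal length")
    rng = np.random.default_rng(spec.seed)
    by_class: dict[str, list[str]] = {}
    excluded: list[str] = [i for i, l in zip(ids, labels) if l is None]
    for cid, label in zip(ids, labels):
        if label is not None:
            by_class.setdefault(label, []).append(cid)

    train: list[str] = []
    test: list[str] = []
    for label in sorted(by_class):
        members = by_class[label]
        n = len(members)
        if n < spec.min_class_size:
            excluded.extend(members)
            continue
        ratio = spec.ratio_small if n <= spec.small_max else spec.ratio_default
        n_train = int(np.floor(ratio * n + 0.5))
        n_train = min(n_train, n - 1)  # always keep >= 1 test member
        order = rng.permutation(n)
        train.extend(members[i] for i in order[:n_train])
        test.extend(members[i] for i in order[n_train:])
    return train, test, excluded


def _default_grid(algorithm: str, n_features: int) -> list[dict]:
    if algorithm == "rf":
        root = max(1, int(round(np.sqrt(n_features))))
        mtry = sorted({max(1, root // 2), root,
                       min(n_features, 2 * root),
                       max(1, n_features // 3)})
        return [{"max_features": m} for m in mtry]
    if algorithm == "svm":
        return [{"C": c} for c in (0.1, 1.0, 10.0, 100.0)]
    if algorithm == "xgboost":
        return [{"max_depth": d} for d in (3, 6)]
    if algorithm == "nb":
        return [{"var_smoothing": v} for v in (1e-9, 1e-6, 1e-3)]
    raise ValidationError(f"unknown algorithm {algorithm!r}; pick from {ALGORITHMS}")


def _base_estimator(algorithm: str, n_trees: int, seed: int | None):
    if algorithm == "rf":
        return RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    if algorithm == "svm":
        return SVC(kernel="rbf", probability=True, random_state=seed)
    if algorithm == "nb":
        return GaussianNB()
    if algorithm == "xgboost":
        from xgboost import XGBClassifier  # optional dependency

        return XGBClassifier(
            n_estimators=200, random_state=seed, eval_metric="mlogloss"
        )
    raise ValidationError(f"unknown algorithm {algorithm!r}; pick from {ALGORITHMS}")


class HerbicideClassifier(BaseEstimator, ClassifierMixin):
    """Multi-class QSAR classifier tuned by grid search under repeated CV.

    Parameters
    ----------
    algorithm : {"rf", "xgboost", "svm", "nb"}
        Base learner; random forest (500 trees, mtry grid) is the default.
    grid : list of dict, optional
        Hyperparameter grid; defaults depend on the algorithm. Grid points
        are evaluated in order and ties on mean CV accuracy go to the
        earliest (least complex) point.
    cv_folds, cv_repeats : int
        Stratified k-fold protocol; folds shrink to the smallest class size
        when a class has fewer members than ``cv_folds``.
    n_trees : int
        Forest size for the RF algorithm.
    random_state : int, optional
        Seed for fold assignment and the base learner.

    Attributes
    ----------
    classes_ : ndarray of class labels (sorted; vocabulary order).
    best_params_ : dict chosen by mean resampled accuracy.
    cv_results_ : DataFrame of per-grid-point mean/sd accuracy.
    resample_scores_ : dict mapping grid index to all fold scores.
    model_ : the refitted base estimator.
    """

    def __init__(
        self,
        algorithm: str = "rf",
        grid: list[dict] | None = None,
        cv_folds: int = 10,
        cv_repeats: int = 10,
        n_trees: int = 500,
        random_state: int | None = None,
    ):
        self.algorithm = algorithm
        self.grid = grid
        self.cv_folds = cv_folds
        self.cv_repeats = cv_repeats
        self.n_trees = n_trees
        self.random_state = random_state

    def fit(self, X, y) -> "HerbicideClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValidationError("X must be 2-D with one row per label")
        self.classes_, counts = np.unique(y, return_counts=True)
        if len(self.classes_) < 2:
            raise ValidationError("need at least 2 classes to train")
        if counts.min() < 2:
            small = self.classes_[counts < 2].tolist()
            raise ValidationError(f"classes with < 2 training members: {small}")

        grid = self.grid if self.grid is not None else _default_grid(
            self.algorithm, X.shape[1]
        )
        folds = min(self.cv_folds, int(counts.min()))
        cv = RepeatedStratifiedKFold(
            n_splits=folds, n_repeats=self.cv_repeats,
            random_state=self.random_state,
        )
        records = []
        self.resample_scores_ = {}
        for gi, params in enumerate(grid):
            est = _base_estimator(self.algorithm, self.n_trees, self.random_state)
            est.set_params(**self._adapt_params(params, y))
            scores = cross_val_score(est, X, self._encode(y), cv=cv,
                                     scoring="accuracy")
            self.resample_scores_[gi] = scores
            records.append({"grid_index": gi, **params,
                            "mean_accuracy": scores.mean(),
                            "sd_accuracy": scores.std(ddof=1)})
        self.cv_results_ = pd.DataFrame(records)
        best = int(np.argmax([r["mean_accuracy"] for r in records]))
        self.best_index_ = best
        self.best_params_ = dict(grid[best])
        self.cv_accuracy_ = float(records[best]["mean_accuracy"])

        self.model_ = _base_estimator(self.algorithm, self.n_trees, self.random_state)
        self.model_.set_params(**self._adapt_params(self.best_params_, y))
        self.model_.fit(X, self._encode(y))
        self.n_features_in_ = X.shape[1]
        return self

    # xgboost needs integer-coded labels; others take strings directly
    def _encode(self, y: np.ndarray) -> np.ndarray:
        if self.algorithm == "xgboost":
            return np.searchsorted(self.classes_, y)
        return y

    def _decode(self, y: np.ndarray) -> np.ndarray:
        if self.algorithm == "xgboost":
            return self.classes_[np.asarray(y, dtype=int)]
        return y

    def _adapt_params(self, params: dict, y: np.ndarray) -> dict:
        if self.algorithm == "xgboost":
            return {**params, "num_class": len(np.unique(y)),
                    "objective": "multi:softprob"}
        return params

    def _check_X(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise ValidationError("classifier is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"feature columns must match training ({self.n_features_in_})"
            )
        return X

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(self._check_X(X))
        # argmax ties break toward the earliest label in vocabulary order
        return self.classes_[np.argmax(proba, axis=1)]

    def predict_proba(self, X) -> np.ndarray:
        X = self._check_X(X)
        proba = self.model_.predict_proba(X)
        order = np.argsort(np.argsort(self.classes_))
        del order  # classes_ already sorted; model_.classes_ matches encode order
        return proba


@dataclass
class ClassifierBundle:
    """A trained classifier plus everything needed to apply and gate it.

    Bundles keep the training representation (fingerprint bits and/or scaled
    descriptor matrix with its scaling statistics) so that
    applicability-domain distances are computed against exactly the data the
    model saw.
    """

    algorithm: str
    estimator: HerbicideClassifier
    label_field: str
    classes: list[str]
    feature_names: list[str]
    training_features: np.ndarray
    training_ids: list[str] = field(default_factory=list)
    retained_keys: list[int] | None = None          # set for fingerprint models
    scaling_stats: ScalingStats | None = None       # set for descriptor models
    resample_records: pd.DataFrame | None = None

    def predict_with_probabilities(
        self, X
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(probability matrix, per-row max probability, argmax labels)."""
        proba = self.estimator.predict_proba(X)
        max_prob = proba.max(axis=1)
        labels = np.asarray(self.classes)[np.argmax(proba, axis=1)]
        return proba, max_prob, labels


def tune_and_train(
    X,
    y,
    algorithm: str = "rf",
    grid: list[dict] | None = None,
    cv: Mapping[str, int] | None = None,
    seed: int | None = None,
    label_field: str = "label",
    feature_names: Sequence[str] | None = None,
    training_ids: Sequence[str] | None = None,
    retained_keys: Sequence[int] | None = None,
    scaling_stats: ScalingStats | None = None,
    n_trees: int = 500,
) -> ClassifierBundle:
    """Grid-search, cross-validate and refit a classifier; return its bundle.

    ``cv`` takes ``{"folds": 10, "repeats": 10}`` (the default protocol);
    hyperparameters are chosen by mean resampled accuracy and the final model
    is refit on the entire training set.
    """
    cv = dict(cv or {"folds": 10, "repeats": 10})
    est = HerbicideClassifier(
        algorithm=algorithm, grid=grid,
        cv_folds=cv.get("folds", 10), cv_repeats=cv.get("repeats", 10),
        n_trees=n_trees, random_state=seed,
    )
    X = np.asarray(X, dtype=float)
    est.fit(X, y)
    return ClassifierBundle(
        algorithm=algorithm,
        estimator=est,
        label_field=label_field,
        classes=[str(c) for c in est.classes_],
        feature_names=list(feature_names) if feature_names is not None
        else [f"x{i}" for i in range(X.shape[1])],
        training_features=X,
        training_ids=list(training_ids) if training_ids is not None else [],
        retained_keys=list(retained_keys) if retained_keys is not None else None,
        scaling_stats=scaling_stats,
        resample_records=est.cv_results_,
    )


def class_probabilities(
    bundle: ClassifierBundle | HerbicideClassifier, X
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Probability matrix with per-row maximum and argmax label.

    For a random forest the probability of a class is the fraction of trees
    voting for it; rows sum to one and argmax ties break toward the earliest
    label in vocabulary order.
    """
    if isinstance(bundle, ClassifierBundle):
        return bundle.predict_with_probabilities(X)
    proba = bundle.predict_proba(X)
    return proba, proba.max(axis=1), bundle.classes_[np.argmax(proba, axis=1)]


@dataclass
class ClassMetrics:
    """One-vs-rest confusion counts and derived rates for one class."""

    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    accuracy: float
    balanced_accuracy: float
    kappa: float
    degenerate: list[str] = field(default_factory=list)


def confusion_metrics(y_true, y_pred, positive_class) -> ClassMetrics:
    """One-vs-rest confusion counts and the printed performance formulas.

    Sensitivity = TP/(TP+FN); Precision = TP/(TP+FP); Specificity =
    TN/(TN+FP); Accuracy = (TP+TN)/n; F1 = 2·Recall·Precision /
    (Recall+Precision); Cohen's kappa = (Po - Pe)/(1 - Pe) with
    Po the accuracy and Pe = ((TP+FN)(TP+FP) + (FP+TN)(FN+TN)) / n².
    Zero denominators yield a rate of 0 with the rate name recorded in
    ``degenerate``.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred must have equal length")
    if y_true.size == 0:
        raise ValidationError("empty inputs")
    pos_t = y_true == positive_class
    pos_p = y_pred == positive_class
    tp = int(np.sum(pos_t & pos_p))
    fn = int(np.sum(pos_t & ~pos_p))
    fp = int(np.sum(~pos_t & pos_p))
    tn = int(np.sum(~pos_t & ~pos_p))
    n = tp + tn + fp + fn

    degenerate: list[str] = []

    def rate(num: float, den: float, name: str) -> float:
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    sens = rate(tp, tp + fn, "sensitivity")
    spec = rate(tn, tn + fp, "specificity")
    prec = rate(tp, tp + fp, "precision")
    acc = (tp + tn) / n
    f1 = rate(2 * sens * prec, sens + prec, "f1")
    pe = ((tp + fn) * (tp + fp) + (fp + tn) * (fn + tn)) / n**2
    kappa = rate(acc - pe, 1 - pe, "kappa")
    return ClassMetrics(
        tp=tp, tn=tn, fp=fp, fn=fn,
        sensitivity=sens, specificity=spec, precision=prec, f1=f1,
        accuracy=acc, balanced_accuracy=(sens + spec) / 2,
        kappa=kappa, degenerate=degenerate,
    )


@dataclass
class MetricRecord:
    """Per-class metrics with macro averages and overall multi-class scores."""

    per_class: dict[str, ClassMetrics]
    macro: dict[str, float]
    overall_accuracy: float
    kappa: float

    def to_frame(self) -> pd.DataFrame:
        rows = {
            label: {
                "sensitivity": m.sensitivity, "specificity": m.specificity,
                "precision": m.precision, "f1": m.f1,
                "balanced_accuracy": m.balanced_accuracy,
            }
            for label, m in self.per_class.items()
        }
        frame = pd.DataFrame(rows).T
        frame.loc["macro_average"] = self.macro
        return frame


def multiclass_kappa(y_true, y_pred) -> float:
    """Unweighted Cohen's kappa on the full multi-class confusion matrix."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = np.unique(np.concatenate([y_true, y_pred]))
    n = y_true.size
    idx = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)))
    for t, p in zip(y_true, y_pred):
        confusion[idx[t], idx[p]] += 1
    po = np.trace(confusion) / n
    pe = float(np.sum(confusion.sum(axis=1) * confusion.sum(axis=0))) / n**2
    if pe == 1:
        return 0.0
    return float((po - pe) / (1 - pe))


def multiclass_report(y_true, y_pred, probs: np.ndarray | None = None) -> MetricRecord:
    """Per-class one-vs-rest metrics, macro averages, accuracy and kappa."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValidationError("empty inputs")
    classes = np.unique(y_true)
    per_class = {str(c): confusion_metrics(y_true, y_pred, c) for c in classes}
    macro = {
        name: float(np.mean([getattr(m, name) for m in per_class.values()]))
        for name in ("sensitivity", "specificity", "precision", "f1",
                     "balanced_accuracy")
    }
    overall = float(np.mean(y_true == y_pred))
    return MetricRecord(
        per_class=per_class, macro=macro,
        overall_accuracy=overall, kappa=multiclass_kappa(y_true, y_pred),
    )
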