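"""Classification and evaluation: KNN / decision tree, stratified 10-fold
cross-validation, and the three performance metrics (accuracy, macro
one-vs-rest specificity, macro one-vs-rest AUC, all in percent).

Estimators come from scikit-learn.  Per fold, feature columns are min-max
scaled with statistics fit on the training split only, so no test-fold
information leaks into the scaling; the classifier then never sees test data
before prediction.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import MinMaxScaler
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "FeatureTable",
    "ClassifierSpec",
    "MetricsReport",
    "knn_classify",
    "tree_classify",
    "cross_validate",
    "compute_metrics",
]


@dataclass
class FeatureTable:
    """Trials-by-features matrix with labels and feature names."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y)
        if self.X.shape[0] != len(self.y):
            raise ValueError("one label per row required")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature table contains non-finite values")
        if len(np.unique(self.y)) < 2:
            raise ValueError("need at least two classes")
        if not self.feature_names:
            self.feature_names = [f"f{i + 1}" for i in range(self.X.shape[1])]
        elif len(self.feature_names) != self.X.shape[1]:
            raise ValueError("one name per feature column required")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "label", self.y)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureTable":
        return cls(df.drop(columns="label").to_numpy(), df["label"].to_numpy(),
                   list(df.columns.drop("label")))


@dataclass(frozen=True)
class ClassifierSpec:
    """Which estimator to run and with what knobs."""

    model: str = "knn"          # "knn" | "tree"
    k: int = 5
    max_depth: int | None = None
    min_leaf: int = 1

    def build(self, seed: int | None = None):
        if self.model == "knn":
            if self.k < 1:
                raise ValueError("k must be >= 1")
            return KNeighborsClassifier(n_neighbors=self.k)
        if self.model == "tree":
            return DecisionTreeClassifier(
                criterion="gini", max_depth=self.max_depth,
                min_samples_leaf=self.min_leaf, random_state=seed)
        raise ValueError(f"unknown model {self.model!r}")


@dataclass
class MetricsReport:
    """Per-fold and aggregate metrics plus a configuration fingerprint."""

    fold_accuracy: np.ndarray       # percent
    fold_specificity: np.ndarray
    fold_auc: np.ndarray
    confusion: np.ndarray           # summed over folds
    classes: np.ndarray
    fingerprint: str

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def specificity(self) -> float:
        return float(np.mean(self.fold_specificity))

    @property
    def auc(self) -> float:
        return float(np.mean(self.fold_auc))

    def summary(self) -> str:
        return (f"accuracy {self.accuracy:.2f}%  "
                f"specificity {self.specificity:.2f}%  "
                f"AUC {self.auc:.2f}%  [{self.fingerprint}]")


def _fit_predict(spec: ClassifierSpec, Xtr, ytr, Xte, seed=None):
    clf = spec.build(seed)
    clf.fit(Xtr, ytr)
    scores = clf.predict_proba(Xte)
    # deterministic argmax tie-break toward the smaller class index
    pred = clf.classes_[np.argmax(scores, axis=1)]
    return pred, scores, clf.classes_


def knn_classify(train: FeatureTable, test_points, k: int = 5):
    """k-nearest-neighbor prediction (Euclidean, majority vote).

    Returns predicted labels and per-class neighbor vote fractions; vote
    ties resolve toward the smaller class index.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(train.y):
        raise ValueError(f"k={k} exceeds {len(train.y)} training rows")
    return _fit_predict(ClassifierSpec("knn", k=k), train.X, train.y,
                        np.atleast_2d(np.asarray(test_points, dtype=float)))[:2]


def tree_classify(train: FeatureTable, test_points, max_depth: int | None = None,
                  seed: int = 0):
    """Gini decision-tree prediction; scores are leaf class frequencies."""
    spec = ClassifierSpec("tree", max_depth=max_depth)
    return _fit_predict(spec, train.X, train.y,
                        np.atleast_2d(np.asarray(test_points, dtype=float)),
                        seed=seed)[:2]


def compute_metrics(y_true, y_pred, scores, classes) -> tuple[float, float, float]:
    """Accuracy, macro OVR specificity and macro OVR AUC, in percent.

    ``scores[:, c]`` is the score for ``classes[c]``.  A class absent from
    ``y_true`` contributes no AUC term (skipped with a warning).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    scores = np.asarray(scores, dtype=float)
    if not (len(y_true) == len(y_pred) == len(scores)):
        raise ValueError("length mismatch")
    classes = np.asarray(classes)
    acc = float(np.mean(y_true == y_pred)) * 100.0

    cm = confusion_matrix(y_true, y_pred, labels=classes)
    total = cm.sum()
    specs = []
    for c in range(len(classes)):
        tp = cm[c, c]
        fp = cm[:, c].sum() - tp
        fn = cm[c, :].sum() - tp
        tn = total - tp - fp - fn
        if tn + fp > 0:
            specs.append(tn / (tn + fp))
    spec = float(np.mean(specs)) * 100.0

    aucs = []
    for c, name in enumerate(classes):
        mask = y_true == name
        if mask.all() or not mask.any():
            import warnings
            warnings.warn(f"class {name!r} degenerate in y_true; AUC term skipped")
            continue
        aucs.append(roc_auc_score(mask.astype(int), scores[:, c]))
    auc = float(np.mean(aucs)) * 100.0 if aucs else float("nan")
    return acc, spec, auc


def _fingerprint(spec: ClassifierSpec, folds: int, seed: int, shape) -> str:
    blob = f"{spec}|folds={folds}|seed={seed}|shape={shape}"
    return hashlib.sha1(blob.encode()).hexdigest()[:12]


def cross_validate(table: FeatureTable, spec: ClassifierSpec | None = None,
                   folds: int = 10, seed: int = 0) -> MetricsReport:
    """Stratified k-fold evaluation with in-fold min-max feature scaling."""
    spec = spec or ClassifierSpec()
    classes, counts = np.unique(table.y, return_counts=True)
    lacking = classes[counts < folds]
    if lacking.size:
        raise ValueError(
            f"class(es) {list(lacking)} have fewer than {folds} trials; "
            "stratified folding impossible"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs, specs_, aucs = [], [], []
    cm_total = np.zeros((len(classes), len(classes)), dtype=int)
    for tr_idx, te_idx in skf.split(table.X, table.y):
        scaler = MinMaxScaler().fit(table.X[tr_idx])
        Xtr = scaler.transform(table.X[tr_idx])
        Xte = scaler.transform(table.X[te_idx])
        pred, scores, cls = _fit_predict(spec, Xtr, table.y[tr_idx], Xte, seed=seed)
        if len(cls) < len(classes):  # fold missing a class entirely (guarded above)
            full = np.zeros((len(te_idx), len(classes)))
            for ci, name in enumerate(cls):
                full[:, np.searchsorted(classes, name)] = scores[:, ci]
            scores = full
        a, s, u = compute_metrics(table.y[te_idx], pred, scores, classes)
        accs.append(a)
        specs_.append(s)
        aucs.append(u)
        cm_total += confusion_matrix(table.y[te_idx], pred, labels=classes)
    return MetricsReport(
        fold_accuracy=np.array(accs), fold_specificity=np.array(specs_),
        fold_auc=np.array(aucs), confusion=cm_total, classes=classes,
        fingerprint=_fingerprint(spec, folds, seed, table.X.shape),
    )
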