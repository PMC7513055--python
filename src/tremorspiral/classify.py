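"""Cross-validated classification and its error metrics.

Three classifiers are evaluated under stratified 10-fold
cross-validation, with features standardised inside each training fold:

* SVM with polynomial kernel of degree 1 (i.e. linear), C = 1;
* a single-hidden-layer MLP with NNHL = max(n_features, n_classes)
  hidden units trained for NNHL x 10 epochs;
* 1-nearest-neighbour with Euclidean distance.

Metrics: accuracy (Acc, %), classification error rate CER = 100 - Acc,
per-class accuracy from the confusion matrix, the accumulated CER
(ACCER) across a list of experiments, and coverage — the percentage of
cases whose true class lies in the smallest predicted-probability class
set reaching 95%.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ValidationError
from .linear_features import FeatureMatrix

CLASSIFIER_KINDS = ("svm_poly", "mlp", "knn")


@dataclass(frozen=True)
class ClassifierConfig:
    """Hyper-parameters for one classifier."""

    kind: str  # svm_poly | mlp | knn
    svm_degree: int = 1
    svm_c: float = 1.0
    mlp_hidden: int | None = None  # NNHL; derived from data when None
    mlp_rule: str = "max"  # max(n_features, n_classes) or "mean"
    training_steps: int | None = None  # TS; NNHL * 10 when None
    knn_k: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValidationError(f"unknown classifier kind {self.kind!r}")
        if self.knn_k < 1:
            raise ValidationError("knn_k must be >= 1")

    def nnhl(self, n_features: int, n_classes: int) -> int:
        if self.mlp_hidden is not None:
            return self.mlp_hidden
        if self.mlp_rule == "mean":
            return max(1, math.ceil((n_features + n_classes) / 2))
        return max(n_features, n_classes)

    def build(self, n_features: int, n_classes: int) -> Pipeline:
        if self.kind == "svm_poly":
            clf = SVC(
                kernel="poly",
                degree=self.svm_degree,
                C=self.svm_c,
                gamma="scale",
                coef0=1.0,
            )
        elif self.kind == "mlp":
            nnhl = self.nnhl(n_features, n_classes)
            ts = self.training_steps if self.training_steps is not None else nnhl * 10
            clf = MLPClassifier(
                hidden_layer_sizes=(nnhl,),
                max_iter=ts,
                random_state=self.seed,
            )
        else:
            clf = KNeighborsClassifier(n_neighbors=self.knn_k, metric="euclidean")
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def default_classifier_grid(seed: int = 0) -> dict[str, ClassifierConfig]:
    return {
        "SVM": ClassifierConfig(kind="svm_poly", seed=seed),
        "MLP": ClassifierConfig(kind="mlp", seed=seed),
        "kNN": ClassifierConfig(kind="knn", seed=seed),
    }


@dataclass
class EvalReport:
    """Pooled cross-validation outcome of one (features, classifier) cell."""

    overall_acc: float  # percent
    per_class_acc: dict[str, float] | None
    confusion: pd.DataFrame  # rows = true class, columns = predicted
    coverage95: float
    folds: int
    seed: int
    n: int
    classifier: str = ""
    feature_set: str = ""
    n_features: int = 0

    @property
    def cer(self) -> float:
        return 100.0 - self.overall_acc

    def to_row(self) -> dict:
        row = {
            "feature_set": self.feature_set,
            "classifier": self.classifier,
            "NF": self.n_features,
            "Acc": self.overall_acc,
            "CER": self.cer,
            "coverage95": self.coverage95,
        }
        if self.per_class_acc:
            for cls, acc in self.per_class_acc.items():
                row[f"Acc_{cls}"] = acc
        return row


def _probabilities(model: Pipeline, X: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Class probabilities; margin classifiers get a logistic link on the
    decision value as an approximation of calibrated scores."""
    clf = model.named_steps["clf"]
    if hasattr(clf, "predict_proba"):
        proba = model.predict_proba(X)
        model_classes = model.named_steps["clf"].classes_
    else:
        d = model.decision_function(X)
        if d.ndim == 1:  # binary: d > 0 means second class
            p1 = 1.0 / (1.0 + np.exp(-d))
            proba = np.column_stack([1.0 - p1, p1])
        else:
            e = np.exp(d - d.max(axis=1, keepdims=True))
            proba = e / e.sum(axis=1, keepdims=True)
        model_classes = clf.classes_
    # align to the global class order
    order = [list(model_classes).index(c) for c in classes]
    return proba[:, order]


def _coverage95(proba: np.ndarray, y_true_idx: np.ndarray) -> float:
    """Percent of rows whose true class lies in the smallest class set
    whose cumulative predicted probability reaches 0.95."""
    covered = 0
    for p, yi in zip(proba, y_true_idx):
        order = np.argsort(p)[::-1]
        cum = 0.0
        in_set = False
        for cls_idx in order:
            cum += p[cls_idx]
            if cls_idx == yi:
                in_set = True
            if cum >= 0.95 - 1e-12:
                break
        if in_set:
            covered += 1
    return 100.0 * covered / len(y_true_idx)


def evaluate(
    matrix: FeatureMatrix | pd.DataFrame | np.ndarray,
    labels=None,
    config: ClassifierConfig | None = None,
    folds: int = 10,
    seed: int = 0,
    fold_selector=None,
) -> EvalReport:
    """Stratified k-fold cross-validation with pooled predictions.

    ``fold_selector``, when given, is called per fold with the training
    block ``(X_train, y_train)`` and must return column indices to use —
    the leakage-free variant of univariate selection.
    """
    if isinstance(matrix, FeatureMatrix):
        X = matrix.X.to_numpy(dtype=float)
        y = matrix.labels.to_numpy() if labels is None else np.asarray(labels)
    else:
        X = np.asarray(matrix, dtype=float)
        if labels is None:
            raise ValidationError("labels are required")
        y = np.asarray(labels)
    if config is None:
        config = ClassifierConfig(kind="knn", seed=seed)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValidationError("labels contain a single class")
    if len(y) < folds:
        raise ValidationError(f"{len(y)} rows cannot be split into {folds} folds")
    class_to_idx = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([class_to_idx[c] for c in y])

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty(len(y), dtype=int)
    proba = np.empty((len(y), len(classes)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence chatter
        for train, test in skf.split(X, y_idx):
            cols = (
                np.arange(X.shape[1])
                if fold_selector is None
                else np.asarray(fold_selector(X[train], y[train]))
            )
            if len(cols) == 0:  # nothing survived selection in this fold
                cols = np.arange(X.shape[1])
            model = config.build(len(cols), len(classes))
            model.fit(X[np.ix_(train, cols)], y_idx[train])
            pred[test] = model.predict(X[np.ix_(test, cols)])
            proba[test] = _probabilities(
                model, X[np.ix_(test, cols)], np.arange(len(classes))
            )

    correct = pred == y_idx
    acc = 100.0 * correct.mean()
    conf = pd.DataFrame(
        0, index=list(classes), columns=list(classes), dtype=int
    )
    for yt, yp in zip(y_idx, pred):
        conf.iloc[yt, yp] += 1
    per_class = {
        str(c): 100.0 * conf.iloc[i, i] / conf.iloc[i].sum()
        for i, c in enumerate(classes)
    }
    return EvalReport(
        overall_acc=float(acc),
        per_class_acc=per_class,
        confusion=conf,
        coverage95=_coverage95(proba, y_idx),
        folds=folds,
        seed=seed,
        n=len(y),
        classifier=config.kind,
        n_features=X.shape[1],
    )


def accumulate_cer(reports: list[EvalReport], per_class: bool = False):
    """ACCER: CERs summed over a list of experiments.

    With ``per_class`` the per-class error rates (100 - per-class
    accuracy) are summed instead, returning a dict per class.
    """
    if not reports:
        raise ValidationError("empty report list")
    if not per_class:
        return float(sum(r.cer for r in reports))
    out: dict[str, float] = {}
    for r in reports:
        if not r.per_class_acc:
            raise ValidationError("per-class ACCER requested on overall-only reports")
        for cls, acc in r.per_class_acc.items():
            out[cls] = out.get(cls, 0.0) + (100.0 - acc)
    return out


def run_experiment_grid(
    matrix: FeatureMatrix,
    feature_sets: dict[str, list[str]],
    configs: dict[str, ClassifierConfig],
    folds: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[tuple[str, str], EvalReport]]:
    """Evaluate every (feature set x classifier) cell.

    Returns the results table (one row per cell) and the full reports.
    """
    reports: dict[tuple[str, str], EvalReport] = {}
    rows = []
    for set_name, columns in feature_sets.items():
        sub = matrix.subset(list(columns))
        for clf_name, cfg in configs.items():
            rep = evaluate(sub, config=replace(cfg, seed=seed), folds=folds, seed=seed)
            rep.feature_set = set_name
            rep.classifier = clf_name
            reports[(set_name, clf_name)] = rep
            rows.append(rep.to_row())
    return pd.DataFrame(rows), reports
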