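"""Balanced random-forest classification of single cells from OMI variables.

Protocol: classes are balanced by randomly undersampling every category to
the minority-class count, the balanced table is split 70/30 into train and
test cells, and a random forest is trained on the 10 OMI variables.  The
one-vs-rest view comes from per-class probability outputs: each class's
continuous score against the rest yields a ROC curve and AUC, alongside
accuracy, per-class precision/recall, row-normalized confusion matrices and
feature importances.  Balancing before the split keeps test sets balanced
too, so accuracy is comparable across classes; balancing after the split is
available for strict train-only undersampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    auc,
    confusion_matrix,
    precision_score,
    recall_score,
    roc_curve,
)
from sklearn.utils.validation import check_is_fitted

from .simulate import OMI_VARIABLES


def balance_classes(
    table: pd.DataFrame, label_column: str, rng_seed: int = 0
) -> pd.DataFrame:
    """Randomly undersample every class to the minority-class count.

    Sampling is without replacement and deterministic under ``rng_seed``;
    the result has exactly min-class-count rows per class.
    """
    counts = table[label_column].value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 classes to balance")
    n_min = int(counts.min())
    rng = np.random.default_rng(rng_seed)
    parts = []
    for cls, sub in table.groupby(label_column, observed=True):
        idx = rng.choice(len(sub), size=n_min, replace=False)
        parts.append(sub.iloc[np.sort(idx)])
    return pd.concat(parts).reset_index(drop=True)


def split_train_test(
    table: pd.DataFrame, train_fraction: float = 0.7, rng_seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random disjoint train/test partition over cells.

    Train size is floor(n * train_fraction); the split is uniform over
    cells (not stratified) and deterministic under ``rng_seed``.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(table)
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(n * train_fraction))
    train = table.iloc[np.sort(perm[:n_train])].reset_index(drop=True)
    test = table.iloc[np.sort(perm[n_train:])].reset_index(drop=True)
    return train, test


def binary_auc(labels, scores) -> float:
    """AUC of a binary one-vs-rest score by trapezoidal ROC integration.

    With tied scores the threshold sweep interpolates linearly, so a
    constant score yields 0.5; equals the Mann-Whitney pairwise-ordering
    probability (ties counted half).
    """
    labels = np.asarray(labels).astype(int)
    fpr, tpr, _ = roc_curve(labels, np.asarray(scores, dtype=float))
    return float(auc(fpr, tpr))


class BalancedRandomForest(BaseEstimator, ClassifierMixin):
    """Random forest over OMI variables with per-class one-vs-rest scores.

    A single multi-class forest whose per-class probabilities serve as the
    one-vs-rest continuous scores (``ovr_mode="probability"``), or one
    literal binary forest per class (``ovr_mode="per_class"``).  Tree count
    and depth are conventional defaults; they are not tuned.
    """

    def __init__(
        self,
        variables: tuple = tuple(OMI_VARIABLES),
        n_trees: int = 500,
        max_depth: int | None = None,
        rng_seed: int = 0,
        ovr_mode: str = "probability",
    ):
        self.variables = variables
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.rng_seed = rng_seed
        self.ovr_mode = ovr_mode

    def _make_forest(self, seed: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_trees,
            max_depth=self.max_depth,
            max_features="sqrt",
            random_state=seed,
            n_jobs=1,
        )

    def fit(self, X, y):
        X, y = self._coerce(X), np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes in the training data")
        if self.ovr_mode == "probability":
            self.forest_ = self._make_forest(self.rng_seed).fit(X, y)
            self.feature_importances_ = self.forest_.feature_importances_
        elif self.ovr_mode == "per_class":
            self.forests_ = {}
            for i, cls in enumerate(self.classes_):
                f = self._make_forest(self.rng_seed + i)
                f.fit(X, (y == cls).astype(int))
                self.forests_[cls] = f
            self.feature_importances_ = np.mean(
                [f.feature_importances_ for f in self.forests_.values()], axis=0
            )
        else:
            raise ValueError(f"unknown ovr_mode {self.ovr_mode!r}")
        return self

    def _coerce(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [v for v in self.variables if v not in X.columns]
            if missing:
                raise KeyError(f"missing feature columns: {missing}")
            return X[list(self.variables)].to_numpy(dtype=float)
        return np.asarray(X, dtype=float)

    def predict_proba(self, X):
        check_is_fitted(self, "classes_")
        X = self._coerce(X)
        if self.ovr_mode == "probability":
            return self.forest_.predict_proba(X)
        scores = np.column_stack(
            [self.forests_[cls].predict_proba(X)[:, 1] for cls in self.classes_]
        )
        total = scores.sum(axis=1, keepdims=True)
        return np.divide(scores, total, out=np.full_like(scores, 1 / scores.shape[1]), where=total > 0)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


@dataclass
class ClassificationReport:
    """Per-class ROC/AUC plus aggregate test metrics for one fitted model."""

    classes: list
    auc: dict  # class -> AUC of the one-vs-rest score
    roc: dict  # class -> (fpr, tpr) arrays
    confusion: np.ndarray  # counts, rows = true class
    confusion_pct: np.ndarray  # row percentages
    accuracy: float
    precision: dict  # class -> precision (NaN if undefined)
    recall: dict
    feature_importances: dict  # variable -> importance (sums to 1)
    class_sizes_before: dict
    class_sizes_after: dict
    rng_seed: int

    def to_dict(self) -> dict:
        return {
            "classes": [str(c) for c in self.classes],
            "auc": {str(k): v for k, v in self.auc.items()},
            "roc": {
                str(k): {"fpr": list(map(float, f)), "tpr": list(map(float, t))}
                for k, (f, t) in self.roc.items()
            },
            "confusion": self.confusion.tolist(),
            "confusion_pct": self.confusion_pct.tolist(),
            "accuracy": self.accuracy,
            "precision": {str(k): v for k, v in self.precision.items()},
            "recall": {str(k): v for k, v in self.recall.items()},
            "feature_importances": self.feature_importances,
            "class_sizes_before": {str(k): v for k, v in self.class_sizes_before.items()},
            "class_sizes_after": {str(k): v for k, v in self.class_sizes_after.items()},
            "rng_seed": self.rng_seed,
        }


def train_one_vs_rest(
    train: pd.DataFrame,
    label_column: str,
    variables: list[str] | None = None,
    n_trees: int = 500,
    rng_seed: int = 0,
    ovr_mode: str = "probability",
) -> BalancedRandomForest:
    """Fit the forest on a (typically balanced) training table."""
    variables = variables or OMI_VARIABLES
    model = BalancedRandomForest(
        variables=tuple(variables), n_trees=n_trees, rng_seed=rng_seed, ovr_mode=ovr_mode
    )
    return model.fit(train, train[label_column].to_numpy())


def evaluate(
    model: BalancedRandomForest,
    test: pd.DataFrame,
    label_column: str,
    class_sizes_before: dict | None = None,
    class_sizes_after: dict | None = None,
) -> ClassificationReport:
    """Score a held-out test table: ROC/AUC per class, confusion, accuracy.

    AUC uses trapezoidal integration of the threshold-swept ROC; hard labels
    are the argmax of per-class scores.  Metrics for a class absent from the
    test set are NaN.
    """
    y = test[label_column].to_numpy()
    proba = model.predict_proba(test)
    pred = model.classes_[np.argmax(proba, axis=1)]
    classes = list(model.classes_)

    aucs, rocs = {}, {}
    for i, cls in enumerate(classes):
        pos = (y == cls).astype(int)
        if pos.sum() == 0 or pos.sum() == len(pos):
            aucs[cls], rocs[cls] = np.nan, (np.array([]), np.array([]))
            continue
        fpr, tpr, _ = roc_curve(pos, proba[:, i])
        aucs[cls] = float(auc(fpr, tpr))
        rocs[cls] = (fpr, tpr)

    cm = confusion_matrix(y, pred, labels=classes)
    row_sums = cm.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        cm_pct = 100.0 * cm / row_sums
    prec = precision_score(y, pred, labels=classes, average=None, zero_division=np.nan)
    rec = recall_score(y, pred, labels=classes, average=None, zero_division=np.nan)
    imp = model.feature_importances_
    return ClassificationReport(
        classes=classes,
        auc=aucs,
        roc=rocs,
        confusion=cm,
        confusion_pct=cm_pct,
        accuracy=float((pred == y).mean()),
        precision={c: float(p) for c, p in zip(classes, prec)},
        recall={c: float(r) for c, r in zip(classes, rec)},
        feature_importances={
            v: float(w) for v, w in zip(model.variables, imp)
        },
        class_sizes_before=class_sizes_before or {},
        class_sizes_after=class_sizes_after or {},
        rng_seed=model.rng_seed,
    )


def run_classification(
    table: pd.DataFrame,
    label_column: str,
    variables: list[str] | None = None,
    train_fraction: float = 0.7,
    n_trees: int = 500,
    rng_seed: int = 0,
    balance: bool = True,
    balance_order: str = "before_split",
) -> ClassificationReport:
    """Full protocol: undersample, 70/30 split, train, evaluate.

    ``balance_order`` chooses whether undersampling precedes the split
    (default; test sets stay balanced) or is applied to the training split
    only ("after_split").
    """
    sizes_before = table[label_column].value_counts().to_dict()
    work = table
    if balance and balance_order == "before_split":
        work = balance_classes(work, label_column, rng_seed)
    train, test = split_train_test(work, train_fraction, rng_seed)
    if balance and balance_order == "after_split":
        train = balance_classes(train, label_column, rng_seed)
    if set(test[label_column]) - set(train[label_column]):
        raise ValueError("a test class is absent from the training split")
    sizes_after = train[label_column].value_counts().to_dict()
    model = train_one_vs_rest(
        train, label_column, variables, n_trees=n_trees, rng_seed=rng_seed
    )
    return evaluate(model, test, label_column, sizes_before, sizes_after)


def repeated_evaluation(
    table: pd.DataFrame,
    label_column: str,
    n_repeats: int = 5,
    rng_seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Re-run the protocol on different random splits to check consistency.

    Returns one row per rerun; ``DataFrame.attrs["summary"]`` holds the
    mean and SD of every metric over the reruns.
    """
    rows = []
    for k in range(n_repeats):
        rep = run_classification(
            table, label_column, rng_seed=rng_seed + k, **kwargs
        )
        row = {"rng_seed": rng_seed + k, "accuracy": rep.accuracy}
        for cls in rep.classes:
            row[f"auc_{cls}"] = rep.auc[cls]
            row[f"recall_{cls}"] = rep.recall[cls]
        rows.append(row)
    df = pd.DataFrame(rows)
    metrics = [c for c in df.columns if c != "rng_seed"]
    df.attrs["summary"] = {
        m: {"mean": float(df[m].mean()), "sd": float(df[m].std(ddof=1))}
        for m in metrics
    }
    return df
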