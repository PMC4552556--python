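"""Confusion-matrix metrics and stratified cross-validation.

The report mirrors the goodness-of-fit block used for the published model:
overall accuracy/error rate, macro-averaged sensitivity (recall) and
specificity (one-vs-rest TN/(TN+FP)), Cohen's kappa and per-class error
rates, plus the forest's out-of-bag error when available.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score, confusion_matrix
from sklearn.model_selection import StratifiedKFold

from .forest import BehaviourForest

__all__ = ["ClassificationReport", "compute_metrics", "cross_validate"]


@dataclass
class ClassificationReport:
    """Metrics derived from one pooled confusion matrix.

    ``confusion`` has true labels on rows and predicted labels on columns;
    proportions (accuracy, errors) are fractions in [0, 1].
    """

    confusion: pd.DataFrame
    accuracy: float
    error_rate: float
    sensitivity: float
    specificity: float
    cohens_kappa: float
    per_class_error: pd.Series
    oob_error: Optional[float] = None
    folds: Optional[int] = None

    @property
    def labels(self) -> list:
        return list(self.confusion.index)

    def largest_confusion_pair(self) -> tuple[str, str, int]:
        """(true, predicted, count) of the largest off-diagonal cell."""
        cm = self.confusion.to_numpy().astype(float).copy()
        np.fill_diagonal(cm, -1.0)
        i, j = np.unravel_index(np.argmax(cm), cm.shape)
        return (
            str(self.confusion.index[i]),
            str(self.confusion.columns[j]),
            int(self.confusion.iloc[i, j]),
        )

    def to_dict(self) -> dict:
        return {
            "labels": [str(l) for l in self.labels],
            "confusion": self.confusion.to_numpy().tolist(),
            "accuracy": self.accuracy,
            "error_rate": self.error_rate,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "cohens_kappa": self.cohens_kappa,
            "per_class_error": {
                str(k): v for k, v in self.per_class_error.items()
            },
            "oob_error": self.oob_error,
            "folds": self.folds,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


def compute_metrics(
    true_labels: Sequence, predicted_labels: Sequence, labels: Optional[Sequence] = None
) -> ClassificationReport:
    """Build a :class:`ClassificationReport` from label vectors.

    ``sensitivity`` is the unweighted mean of per-class recall,
    ``specificity`` the unweighted mean of per-class TN/(TN+FP); kappa is the
    chance-corrected agreement (p_o - p_e)/(1 - p_e) with p_e from the
    marginal products. Kappa is NaN (with a warning) for single-class input.
    """
    y_true = np.asarray(true_labels)
    y_pred = np.asarray(predicted_labels)
    if len(y_true) != len(y_pred):
        raise ValueError(
            f"label vectors differ in length ({len(y_true)} vs {len(y_pred)})"
        )
    if len(y_true) == 0:
        raise ValueError("empty label vectors")
    if labels is None:
        labels = np.unique(np.concatenate([y_true, y_pred]))
    labels = np.asarray(labels)

    cm = confusion_matrix(y_true, y_pred, labels=labels).astype(int)
    total = cm.sum()
    accuracy = float(np.trace(cm) / total)

    support = cm.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(support > 0, np.diag(cm) / support, np.nan)
    valid = support > 0
    sensitivity = float(np.nanmean(recall[valid]))

    spec = []
    for k in range(len(labels)):
        tn = total - cm[k].sum() - cm[:, k].sum() + cm[k, k]
        fp = cm[:, k].sum() - cm[k, k]
        spec.append(tn / (tn + fp) if (tn + fp) > 0 else np.nan)
    specificity = float(np.nanmean(np.asarray(spec)[valid]))

    if len(np.unique(y_true)) < 2:
        warnings.warn("kappa is undefined for single-class truth", stacklevel=2)
        kappa = float("nan")
    else:
        kappa = float(cohen_kappa_score(y_true, y_pred, labels=labels))

    per_class_error = pd.Series(
        1.0 - recall, index=labels, name="class_error"
    )
    return ClassificationReport(
        confusion=pd.DataFrame(cm, index=labels, columns=labels),
        accuracy=accuracy,
        error_rate=1.0 - accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        cohens_kappa=kappa,
        per_class_error=per_class_error,
    )


def cross_validate(
    features,
    labels,
    k: int = 10,
    *,
    n_trees: int = 500,
    mtry: int = 2,
    seed: Optional[int] = None,
) -> ClassificationReport:
    """Stratified k-fold cross-validation of the forest; pooled confusion.

    Out-of-fold predictions from all folds are pooled into a single
    confusion matrix before computing metrics (fold-averaged metrics hide
    which classes confuse). Deterministic given ``seed``: fold shuffling and
    the per-fold forest seeds all derive from it.
    """
    X = np.asarray(
        features.to_numpy() if isinstance(features, pd.DataFrame) else features,
        dtype=float,
    )
    y = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        small = classes[counts.argmin()]
        raise ValueError(
            f"class {small!r} has {counts.min()} members, fewer than k={k} folds"
        )
    ss = np.random.SeedSequence(seed)
    shuffle_seed, *fold_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(k + 1)
    ]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=shuffle_seed)
    y_pred = np.empty(len(y), dtype=y.dtype)
    for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        model = BehaviourForest(
            n_trees=n_trees, mtry=mtry, random_state=fold_seeds[fold]
        ).fit(X[train_idx], y[train_idx])
        y_pred[test_idx] = model.predict(X[test_idx])
    report = compute_metrics(y, y_pred, labels=classes)
    report.folds = k
    return report
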