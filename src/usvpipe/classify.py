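"""Supervised acoustic-feature classification into the five call types.

A multiclass learner over contour-derived acoustic parameters assigns one
of the repertoire labels to each detection.  Training reports a held-out
confusion matrix from a seeded, stratified 8:2 learn/test split
(stratification protects the naturally rare Zip class).  The classifier
family is a seeded random forest: deterministic after seeding, strong on
small tabular feature sets, and recorded in the run configuration.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import joblib
import numpy as np
import pandas as pd

from .core import AcousticFeatureVector, features_to_matrix
from .postfilter import _fit_with_holdout


@dataclass
class CallClassifierModel:
    """Fitted multiclass decision function with its training summary."""

    estimator: object
    classes: Tuple[str, ...]
    training_summary: dict

    def save(self, path) -> None:
        joblib.dump({"format": 1, "model": self}, path)

    @classmethod
    def load(cls, path) -> "CallClassifierModel":
        payload = joblib.load(path)
        if payload.get("format") != 1:
            raise ValueError("unrecognized classifier file format")
        return payload["model"]


def train_classifier(
    features: Sequence[AcousticFeatureVector],
    labels: Sequence[str],
    seed: int,
) -> CallClassifierModel:
    """Fit the call-type classifier on labelled features.

    Requires at least two classes; a class with fewer than 10 examples
    triggers a warning but training proceeds (rare, highly stereotyped
    types can still train well from few examples).
    """
    labels = np.asarray(labels, dtype=object)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("classifier training needs at least two classes")
    for cls_name, n in zip(classes, counts):
        if n < 10:
            warnings.warn(
                f"class {cls_name!r} has only {n} training examples", stacklevel=2
            )
    X = features_to_matrix(features)
    estimator, confusion, class_list = _fit_with_holdout(X, labels, seed)
    summary = {
        "class_counts": {c: int(n) for c, n in zip(classes, counts)},
        "classes": class_list,
        "holdout_confusion": confusion,
    }
    return CallClassifierModel(
        estimator=estimator, classes=tuple(class_list), training_summary=summary
    )


def classify(
    model: CallClassifierModel, features: Sequence[AcousticFeatureVector]
) -> Tuple[List[str], pd.DataFrame]:
    """Predict one label per detection plus per-class scores.

    Deterministic given the model and features; empty input yields empty
    output.
    """
    if len(features) == 0:
        return [], pd.DataFrame(columns=list(model.classes))
    X = features_to_matrix(features)
    if X.shape[1] != model.estimator.n_features_in_:
        raise ValueError(
            f"feature dimensionality {X.shape[1]} does not match the model "
            f"({model.estimator.n_features_in_})"
        )
    labels = model.estimator.predict(X).tolist()
    scores = pd.DataFrame(
        model.estimator.predict_proba(X), columns=list(model.estimator.classes_)
    )
    return labels, scores


def confusion_matrix(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    class_list: Sequence[str] = None,
) -> dict:
    """Counts matrix (rows = true, columns = predicted) with per-class metrics.

    Per-class precision is the diagonal over the column sum, recall the
    diagonal over the row sum; ``*_pct`` values are rounded to the nearest
    integer percentage for reporting.  Labels outside ``class_list`` are
    rejected.
    """
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences must have equal length")
    if class_list is None:
        class_list = sorted(set(true_labels) | set(predicted_labels))
    else:
        class_list = list(class_list)
        bad = (set(true_labels) | set(predicted_labels)) - set(class_list)
        if bad:
            raise ValueError(f"labels outside the class list: {sorted(bad)}")
    counts = pd.DataFrame(0, index=class_list, columns=class_list, dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        counts.loc[t, p] += 1
    diag = pd.Series(np.diag(counts.values), index=class_list, dtype=float)
    col = counts.sum(axis=0).astype(float)
    row = counts.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = (diag / col).where(col > 0)
        recall = (diag / row).where(row > 0)
    return {
        "counts": counts,
        "precision": precision,
        "recall": recall,
        "precision_pct": (precision * 100).round().astype("Int64"),
        "recall_pct": (recall * 100).round().astype("Int64"),
        "accuracy": float(diag.sum() / max(1, len(true_labels))),
    }


__all__ = ["CallClassifierModel", "train_classifier", "classify", "confusion_matrix"]
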