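"""Detection cleanup: duplicate/fragment filtering and denoising.

Two stages run after multi-profile detection:

* :func:`rds_filter` -- removes *doublet syllables* (short-profile boxes
  that sit inside a longer-profile box, e.g. trill syllables re-reported by
  the short detector) and merges *fragments* (same-profile boxes split by
  brief amplitude dips).  The exact rules are this package's reconstruction
  of the described behavior: containment fraction and merge gap are
  parameters, precedence goes to the longer-duration profile's box.
* :func:`train_denoiser` / :func:`denoise` -- a binary call-vs-noise
  classifier over acoustic features that rejects broadband transients
  (scratching, digging) from the detection list while keeping every box in
  the audit trail with an explicit status.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .core import AcousticFeatureVector, DetectionBox, features_to_matrix, temporal_overlap

#: Rank of each detector profile; higher rank wins containment conflicts.
_PROFILE_RANK = {"very_short": 0, "short": 1, "long": 2}

DEFAULT_MERGE_GAP = 0.015
DEFAULT_CONTAINMENT_FRAC = 0.9

CALL_LABEL = "call"
NOISE_LABEL_BINARY = "noise"


def rds_filter(
    boxes: Sequence[DetectionBox],
    merge_gap: float = DEFAULT_MERGE_GAP,
    containment_frac: float = DEFAULT_CONTAINMENT_FRAC,
) -> List[DetectionBox]:
    """Doublet-syllable removal followed by fragment merging; idempotent.

    A box whose temporal extent is at least ``containment_frac`` contained
    inside a longer box from a longer-duration profile is deleted; boxes of
    the same profile separated by gaps shorter than ``merge_gap`` seconds
    are merged into their union.  Both rules are iterated to a fixpoint so
    reapplying the filter never changes the output.
    """
    current = [
        DetectionBox(
            b.t_start, b.t_end, b.f_low, b.f_high, b.score,
            b.source_detector, b.label, "filtered",
        )
        for b in boxes
    ]
    for _ in range(max(1, len(current))):
        step = _merge_fragments(_remove_contained(current, containment_frac), merge_gap)
        if _same_boxes(step, current):
            break
        current = step
    return sorted(current, key=lambda b: (b.t_start, b.t_end))


def _remove_contained(
    boxes: List[DetectionBox], containment_frac: float
) -> List[DetectionBox]:
    keep: List[DetectionBox] = []
    for b in boxes:
        contained = any(
            c is not b
            and _PROFILE_RANK.get(c.source_detector, 0) > _PROFILE_RANK.get(b.source_detector, 0)
            and c.duration > b.duration
            and temporal_overlap(b.t_start, b.t_end, c.t_start, c.t_end) >= containment_frac * b.duration
            for c in boxes
        )
        if not contained:
            keep.append(b)
    return keep


def _merge_fragments(boxes: List[DetectionBox], merge_gap: float) -> List[DetectionBox]:
    out: List[DetectionBox] = []
    by_profile: Dict[str, List[DetectionBox]] = {}
    for b in boxes:
        by_profile.setdefault(b.source_detector, []).append(b)
    for profile, group in by_profile.items():
        group = sorted(group, key=lambda b: (b.t_start, b.t_end))
        merged = [group[0]]
        for b in group[1:]:
            prev = merged[-1]
            if b.t_start - prev.t_end < merge_gap:
                merged[-1] = DetectionBox(
                    t_start=prev.t_start,
                    t_end=max(prev.t_end, b.t_end),
                    f_low=min(prev.f_low, b.f_low),
                    f_high=max(prev.f_high, b.f_high),
                    score=max(prev.score, b.score),
                    source_detector=profile,
                    label=prev.label,
                    status="filtered",
                )
            else:
                merged.append(b)
        out.extend(merged)
    return out


def _same_boxes(a: List[DetectionBox], b: List[DetectionBox]) -> bool:
    key = lambda x: (x.t_start, x.t_end, x.f_low, x.f_high, x.source_detector)
    return sorted(map(key, a)) == sorted(map(key, b))


@dataclass
class DenoiserModel:
    """Fitted call-vs-noise decision function with its training summary."""

    estimator: RandomForestClassifier
    classes: Tuple[str, ...]
    training_summary: dict

    def predict(self, features: Sequence[AcousticFeatureVector]) -> np.ndarray:
        if len(features) == 0:
            return np.array([], dtype=object)
        return self.estimator.predict(features_to_matrix(features))

    def save(self, path) -> None:
        joblib.dump({"format": 1, "model": self}, path)

    @classmethod
    def load(cls, path) -> "DenoiserModel":
        payload = joblib.load(path)
        if payload.get("format") != 1:
            raise ValueError("unrecognized denoiser file format")
        return payload["model"]


def train_denoiser(
    features: Sequence[AcousticFeatureVector],
    labels: Sequence[str],
    seed: int,
) -> DenoiserModel:
    """Fit the binary denoiser on labelled features (seeded 8:2 split).

    Labels are ``"call"`` (positive) / ``"noise"`` (negative); both classes
    must be present with at least 20 examples each.  The held-out confusion
    matrix from the stratified 8:2 learn/test split is reported in the
    training summary.
    """
    labels = np.asarray(labels, dtype=object)
    counts = {lab: int((labels == lab).sum()) for lab in np.unique(labels)}
    if set(counts) != {CALL_LABEL, NOISE_LABEL_BINARY}:
        raise ValueError(
            f"denoiser training needs both 'call' and 'noise' examples, got {sorted(counts)}"
        )
    if min(counts.values()) < 20:
        raise ValueError("denoiser training needs at least 20 examples per class")
    X = features_to_matrix(features)
    estimator, confusion, classes = _fit_with_holdout(X, labels, seed)
    summary = {
        "n_call": counts[CALL_LABEL],
        "n_noise": counts[NOISE_LABEL_BINARY],
        "classes": classes,
        "holdout_confusion": confusion,
        "holdout_class_accuracy": _per_class_accuracy(confusion),
    }
    return DenoiserModel(estimator=estimator, classes=tuple(classes), training_summary=summary)


def _fit_with_holdout(X: np.ndarray, labels: np.ndarray, seed: int, n_estimators: int = 200):
    """Stratified 8:2 split, fit on the learning subset, held-out confusion."""
    try:
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, labels, test_size=0.2, random_state=seed, stratify=labels
        )
    except ValueError:  # a class too small to stratify
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, labels, test_size=0.2, random_state=seed
        )
    est = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    est.fit(X_tr, y_tr)
    classes = sorted(np.unique(labels).tolist())
    idx = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    for yt, yp in zip(y_te, est.predict(X_te)):
        confusion[idx[yt], idx[yp]] += 1
    return est, confusion, classes


def _per_class_accuracy(confusion: np.ndarray) -> np.ndarray:
    totals = confusion.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        acc = np.diag(confusion) / totals
    return np.where(totals > 0, acc, np.nan)


def denoise(
    boxes: Sequence[DetectionBox],
    features: Sequence[AcousticFeatureVector],
    model: DenoiserModel,
) -> List[DetectionBox]:
    """Reject boxes the denoiser calls noise; return the accepted list.

    Rejected boxes are not deleted: their status is set to ``rejected`` in
    place (the audit trail mirrors a reviewer's accept/reject marks).
    """
    if len(boxes) != len(features):
        raise ValueError("one feature vector per box is required")
    if len(boxes) == 0:
        return []
    predictions = model.predict(features)
    accepted: List[DetectionBox] = []
    for box, pred in zip(boxes, predictions):
        if pred == NOISE_LABEL_BINARY:
            box.status = "rejected"
        else:
            box.status = "accepted"
            accepted.append(box)
    return accepted


__all__ = [
    "rds_filter",
    "DenoiserModel",
    "train_denoiser",
    "denoise",
    "DEFAULT_MERGE_GAP",
    "DEFAULT_CONTAINMENT_FRAC",
    "CALL_LABEL",
    "NOISE_LABEL_BINARY",
]
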