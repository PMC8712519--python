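"""Detector/classifier validation: matching, FP taxonomy, precision/recall.

Detections are matched to ground-truth annotations by temporal
intersection-over-union (IoU) with greedy one-to-one assignment in
descending overlap order.  Unmatched detections fall into the false-positive
taxonomy:

* ``noise_fp`` -- no overlap with any call;
* ``fragment_fp`` -- partial overlap with exactly one call;
* ``cluster_fp`` -- one box spanning two or more calls (typically members
  of a rapid series) without meeting the per-call IoU;
* ``overlaid_fp`` -- one box spanning two temporally superimposed calls of
  different types (counted as a false positive only in the automated mode).

Precision is ``pr = tp / (tp + fp)`` (defined as 1.0 at zero detections)
and recall is ``r = tp / tt`` with *tt* the total number of true calls.
Because ground truth here is exact, recall cannot exceed 1; on real
recordings scored against manual screening it can, since a detector may
find calls the human missed.

The *semi-automated* mode simulates reviewer corrections in a selection
GUI: fragment boxes are extended to the full call, cluster boxes are split
at call boundaries, and an overlaid box counts as a true positive for each
of the superimposed calls.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    CallAnnotation,
    DetectionBox,
    temporal_iou,
    temporal_overlap,
)

DEFAULT_IOU_THRESHOLD = 0.5

TRUE_POSITIVE = "true_positive"
FP_CATEGORIES = ("noise_fp", "fragment_fp", "cluster_fp", "overlaid_fp")
MODES = ("automated", "semi_automated")


@dataclass
class MatchResult:
    """Per-detection categories and per-annotation detection flags."""

    categories: List[str]
    matched_ids: List[List[str]]  # annotation ids each box references
    detected: Dict[str, bool]  # call-annotation id -> detected
    iou_threshold: float

    @property
    def tp(self) -> int:
        return sum(c == TRUE_POSITIVE for c in self.categories)

    @property
    def fp(self) -> int:
        return sum(c != TRUE_POSITIVE for c in self.categories)

    def fp_breakdown(self) -> Dict[str, int]:
        return {cat: sum(c == cat for c in self.categories) for cat in FP_CATEGORIES}


def match_detections(
    boxes: Sequence[DetectionBox],
    annotations: Sequence[CallAnnotation],
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> MatchResult:
    """Categorize every detection against the ground truth of one file.

    A box qualifying (IoU >= threshold) against exactly one call is a
    true-positive candidate; candidates are assigned one-to-one greedily in
    descending overlap order.  Everything else falls into the FP taxonomy
    described in the module docstring.  Noise annotations are not targets:
    a box over one matches nothing and is a ``noise_fp``.
    """
    if not 0.0 < iou_threshold <= 1.0:
        raise ValueError("iou_threshold must lie in (0, 1]")
    calls = [a for a in annotations if not a.is_noise]
    ids = [a.id if a.id is not None else f"a{i:04d}" for i, a in enumerate(calls)]
    overlaid = {
        ids[i]: calls[i].overlaid_with for i in range(len(calls))
    }
    n_boxes, n_calls = len(boxes), len(calls)
    overlap = np.zeros((n_boxes, n_calls))
    iou = np.zeros((n_boxes, n_calls))
    for i, b in enumerate(boxes):
        for j, a in enumerate(calls):
            overlap[i, j] = temporal_overlap(b.t_start, b.t_end, a.t_start, a.t_end)
            iou[i, j] = temporal_iou(b.t_start, b.t_end, a.t_start, a.t_end)

    qualifies = iou >= iou_threshold
    n_qualified = qualifies.sum(axis=1)

    categories = [""] * n_boxes
    matched: List[List[str]] = [[] for _ in range(n_boxes)]
    detected = {aid: False for aid in ids}
    ann_taken = [False] * n_calls

    # overlaid precedence: a box covering both members of an overlaid pair
    # is never a true positive in this (automated) accounting, even if it
    # meets the IoU against one of them
    id_index = {aid: j for j, aid in enumerate(ids)}
    spans_overlay = np.zeros(n_boxes, dtype=bool)
    for i in range(n_boxes):
        for j in np.nonzero(overlap[i] > 0)[0]:
            partner = overlaid.get(ids[j])
            if partner in id_index and overlap[i, id_index[partner]] > 0:
                spans_overlay[i] = True
                break

    # greedy one-to-one TP assignment, descending overlap
    candidates = [
        (overlap[i, j], i, j)
        for i in range(n_boxes)
        for j in range(n_calls)
        if qualifies[i, j] and n_qualified[i] == 1 and not spans_overlay[i]
    ]
    box_taken = [False] * n_boxes
    for ov, i, j in sorted(candidates, key=lambda t: -t[0]):
        if box_taken[i] or ann_taken[j]:
            continue
        box_taken[i] = ann_taken[j] = True
        categories[i] = TRUE_POSITIVE
        matched[i] = [ids[j]]
        detected[ids[j]] = True

    for i in range(n_boxes):
        if categories[i]:
            continue
        touching = np.nonzero(overlap[i] > 0)[0]
        refs = [ids[j] for j in touching]
        matched[i] = refs
        if touching.size == 0:
            categories[i] = "noise_fp"
        elif touching.size == 1:
            categories[i] = "fragment_fp"
        else:
            categories[i] = "overlaid_fp" if spans_overlay[i] else "cluster_fp"
    return MatchResult(
        categories=categories,
        matched_ids=matched,
        detected=detected,
        iou_threshold=iou_threshold,
    )


def precision(tp: int, fp: int) -> float:
    """``pr = tp / (tp + fp)``; 1.0 when there are no detections at all."""
    if tp < 0 or fp < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp == 0:
        return 1.0
    return tp / (tp + fp)


def recall(tp: int, tt: int) -> float:
    """``r = tp / tt`` with *tt* the total number of target calls."""
    if tp < 0:
        raise ValueError("counts must be non-negative")
    if tt <= 0:
        raise ValueError("recall is undefined when there are no target calls (tt = 0)")
    return tp / tt


def semi_automated_adjust(
    match: MatchResult,
    boxes: Sequence[DetectionBox],
    annotations: Sequence[CallAnnotation],
) -> Tuple[List[DetectionBox], MatchResult]:
    """Simulated reviewer corrections; returns adjusted boxes and categories.

    Each fragment box is extended to its call's extent; each cluster box is
    split at call boundaries (one box per member); an overlaid box becomes
    one true positive per superimposed call.  Noise boxes are untouched and
    extra fragments of an already-detected call are merged away.  The
    ground-truth annotations are never altered.
    """
    ann_by_id = {
        (a.id if a.id is not None else f"a{i:04d}"): a
        for i, a in enumerate(p for p in annotations if not p.is_noise)
    }
    out_boxes: List[DetectionBox] = []
    out_categories: List[str] = []
    out_matched: List[List[str]] = []
    detected = dict(match.detected)

    def _add_tp(box: DetectionBox, aid: str) -> None:
        ann = ann_by_id[aid]
        out_boxes.append(
            DetectionBox(
                ann.t_start, ann.t_end, box.f_low, box.f_high,
                box.score, box.source_detector, box.label, "adjusted",
            )
        )
        out_categories.append(TRUE_POSITIVE)
        out_matched.append([aid])
        detected[aid] = True

    for box, category, refs in zip(boxes, match.categories, match.matched_ids):
        if category == TRUE_POSITIVE:
            out_boxes.append(box)
            out_categories.append(category)
            out_matched.append(refs)
        elif category == "fragment_fp":
            (aid,) = refs
            if not detected[aid]:
                _add_tp(box, aid)
            # an extra fragment of an already-corrected call is merged away
        elif category in ("cluster_fp", "overlaid_fp"):
            for aid in refs:
                if not detected[aid]:
                    _add_tp(box, aid)
        else:  # noise_fp: no correction possible
            out_boxes.append(box)
            out_categories.append(category)
            out_matched.append(refs)

    adjusted = MatchResult(
        categories=out_categories,
        matched_ids=out_matched,
        detected=detected,
        iou_threshold=match.iou_threshold,
    )
    return out_boxes, adjusted


@dataclass
class EvaluationReport:
    """Precision/recall tallies for a set of files in one scoring mode."""

    mode: str
    tp: int
    fp: int
    tt: int
    fp_by_category: Dict[str, int]
    precision: float
    recall: float
    per_type: Dict[str, dict]
    per_file: List[dict]
    precision_median: float
    precision_iqr: float
    recall_median: float
    recall_iqr: float


def score_run(
    files: Sequence[Tuple[Sequence[DetectionBox], Sequence[CallAnnotation]]],
    mode: str = "automated",
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> EvaluationReport:
    """Score detections across files; median and IQR summarize the files.

    In ``semi_automated`` mode the reviewer adjustment is applied per file
    before tallying.  A file without target calls contributes no recall
    value (logged as a warning) but still counts toward precision.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if len(files) == 0:
        raise ValueError("score_run needs at least one file")

    per_file: List[dict] = []
    total_tp = total_fp = total_tt = 0
    fp_by_cat = {cat: 0 for cat in FP_CATEGORIES}
    type_tallies: Dict[str, dict] = {}

    for boxes, annotations in files:
        match = match_detections(boxes, annotations, iou_threshold)
        if mode == "semi_automated":
            boxes, match = semi_automated_adjust(match, boxes, annotations)
        calls = [a for a in annotations if not a.is_noise]
        tt = len(calls)
        tp, fp = match.tp, match.fp
        entry = {
            "tp": tp,
            "fp": fp,
            "tt": tt,
            "precision": precision(tp, fp),
            "recall": recall(tp, tt) if tt > 0 else None,
            "fp_by_category": match.fp_breakdown(),
        }
        if tt == 0:
            warnings.warn("file without target calls excluded from recall summary")
        per_file.append(entry)
        total_tp += tp
        total_fp += fp
        total_tt += tt
        for cat, n in match.fp_breakdown().items():
            fp_by_cat[cat] += n

        ann_by_id = {
            (a.id if a.id is not None else f"a{i:04d}"): a for i, a in enumerate(calls)
        }
        for aid, hit in match.detected.items():
            ct = ann_by_id[aid].call_type
            tally = type_tallies.setdefault(ct, {"tp": 0, "tt": 0})
            tally["tt"] += 1
            tally["tp"] += int(hit)

    per_type = {
        ct: {**tally, "recall": recall(tally["tp"], tally["tt"])}
        for ct, tally in sorted(type_tallies.items())
    }
    precisions = [e["precision"] for e in per_file]
    recalls = [e["recall"] for e in per_file if e["recall"] is not None]
    return EvaluationReport(
        mode=mode,
        tp=total_tp,
        fp=total_fp,
        tt=total_tt,
        fp_by_category=fp_by_cat,
        precision=precision(total_tp, total_fp),
        recall=recall(total_tp, total_tt) if total_tt > 0 else float("nan"),
        per_type=per_type,
        per_file=per_file,
        precision_median=float(np.median(precisions)),
        precision_iqr=_iqr(precisions),
        recall_median=float(np.median(recalls)) if recalls else float("nan"),
        recall_iqr=_iqr(recalls) if recalls else float("nan"),
    )


def _iqr(values: Sequence[float]) -> float:
    q75, q25 = np.percentile(values, [75, 25])
    return float(q75 - q25)


__all__ = [
    "MatchResult",
    "EvaluationReport",
    "match_detections",
    "precision",
    "recall",
    "semi_automated_adjust",
    "score_run",
    "DEFAULT_IOU_THRESHOLD",
    "TRUE_POSITIVE",
    "FP_CATEGORIES",
    "MODES",
]
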