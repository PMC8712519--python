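"""Matching, FP taxonomy, precision/recall and the two scoring modes."""
import numpy as np
import pytest

from usvpipe.core import CallAnnotation, DetectionBox
from usvpipe.evaluate import (
    FP_CATEGORIES,
    TRUE_POSITIVE,
    match_detections,
    precision,
    recall,
    score_run,
    semi_automated_adjust,
)


def ann(t0, t1, ct="tsak", aid=None, series=None, overlaid=None):
    return CallAnnotation(t0, t1, 10_000, 30_000, ct, series_id=series,
                          overlaid_with=overlaid, id=aid)


def box(t0, t1):
    return DetectionBox(t0, t1, 10_000, 30_000, 0.9, "short")


class TestMatchDetections:
    def test_exact_box_is_true_positive(self):
        m = match_detections([box(1.0, 1.1)], [ann(1.0, 1.1, aid="a0")], 0.5)
        assert m.categories == [TRUE_POSITIVE]
        assert m.matched_ids == [["a0"]]
        assert m.detected["a0"]

    def test_box_spanning_series_is_cluster_fp(self):
        """One box over three series members references all three."""
        anns = [ann(0.0, 0.05, aid="a0", series="s"),
                ann(0.15, 0.20, aid="a1", series="s"),
                ann(0.30, 0.35, aid="a2", series="s")]
        m = match_detections([box(0.0, 0.35)], anns, 0.5)
        assert m.categories == ["cluster_fp"]
        assert sorted(m.matched_ids[0]) == ["a0", "a1", "a2"]

    def test_box_in_noise_region_is_noise_fp(self):
        m = match_detections([box(5.0, 5.1)], [ann(1.0, 1.1, aid="a0")], 0.5)
        assert m.categories == ["noise_fp"]

    def test_partial_overlap_is_fragment_fp(self):
        m = match_detections([box(1.0, 1.04)], [ann(1.0, 1.2, aid="a0")], 0.5)
        assert m.categories == ["fragment_fp"]
        assert m.matched_ids == [["a0"]]

    def test_overlaid_pair_never_true_positive(self):
        """A box covering both overlaid calls is overlaid_fp in automated mode."""
        anns = [ann(0.0, 1.0, ct="long_whistle", aid="a0", overlaid="a1"),
                ann(0.4, 1.2, ct="trill", aid="a1", overlaid="a0")]
        m = match_detections([box(0.0, 1.2)], anns, 0.5)
        assert m.categories == ["overlaid_fp"]
        assert sorted(m.matched_ids[0]) == ["a0", "a1"]

    def test_partition_property(self):
        rng = np.random.default_rng(3)
        anns = [ann(i * 0.5, i * 0.5 + 0.2, aid=f"a{i}") for i in range(10)]
        boxes = []
        for _ in range(15):
            t0 = float(rng.uniform(0, 5))
            boxes.append(box(t0, t0 + float(rng.uniform(0.05, 0.6))))
        m = match_detections(boxes, anns, 0.5)
        assert len(m.categories) == len(boxes)
        assert all(c == TRUE_POSITIVE or c in FP_CATEGORIES for c in m.categories)
        assert m.tp + m.fp == len(boxes)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            match_detections([], [], 0.0)


class TestPrecisionRecall:
    def test_zip_worked_example(self):
        assert round(precision(2, 12), 2) == 0.14
        assert recall(2, 2) == 1.0

    def test_denoiser_worked_example(self):
        assert round(recall(62, 63), 2) == 0.98

    @pytest.mark.parametrize("tp,fp,expected", [(7, 0, 1.0), (0, 5, 0.0), (0, 0, 1.0)])
    def test_precision_bounds(self, tp, fp, expected):
        assert precision(tp, fp) == expected

    def test_recall_zero_and_undefined(self):
        assert recall(0, 5) == 0.0
        with pytest.raises(ValueError):
            recall(1, 0)
        with pytest.raises(ValueError):
            precision(-1, 2)

    def test_agreement_with_direct_count_arithmetic(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            tp = int(rng.integers(0, 50))
            fp = int(rng.integers(0, 50))
            tt = int(rng.integers(1, 100))
            assert precision(tp, fp) == (tp / (tp + fp) if tp + fp else 1.0)
            assert recall(tp, tt) == tp / tt


class TestSemiAutomatedAdjust:
    def test_cluster_split_into_members(self):
        anns = [ann(0.0, 0.05, aid="a0", series="s"),
                ann(0.15, 0.20, aid="a1", series="s"),
                ann(0.30, 0.35, aid="a2", series="s")]
        boxes = [box(0.0, 0.35)]
        m = match_detections(boxes, anns, 0.5)
        adj_boxes, adj = semi_automated_adjust(m, boxes, anns)
        assert len(adj_boxes) == 3
        assert adj.categories == [TRUE_POSITIVE] * 3
        assert all(adj.detected.values())
        assert len(adj.detected) == 3  # ground truth never changes size

    def test_fragment_extended_to_annotation(self):
        anns = [ann(1.0, 2.0, ct="long_whistle", aid="a0")]
        boxes = [box(1.0, 1.4)]  # covers 40% of the call
        m = match_detections(boxes, anns, 0.5)
        adj_boxes, adj = semi_automated_adjust(m, boxes, anns)
        assert adj.categories == [TRUE_POSITIVE]
        assert adj_boxes[0].t_start == 1.0 and adj_boxes[0].t_end == 2.0
        assert adj_boxes[0].status == "adjusted"

    def test_clean_true_positives_untouched(self):
        anns = [ann(1.0, 1.1, aid="a0")]
        boxes = [box(1.0, 1.1)]
        m = match_detections(boxes, anns, 0.5)
        adj_boxes, adj = semi_automated_adjust(m, boxes, anns)
        assert adj_boxes == boxes and adj.categories == m.categories

    def test_noise_fp_not_correctable(self):
        anns = [ann(1.0, 1.1, aid="a0")]
        boxes = [box(3.0, 3.1)]
        m = match_detections(boxes, anns, 0.5)
        _, adj = semi_automated_adjust(m, boxes, anns)
        assert adj.categories == ["noise_fp"]


class TestScoreRun:
    def test_single_perfect_file(self):
        anns = [ann(i * 1.0, i * 1.0 + 0.1, aid=f"a{i}") for i in range(5)]
        boxes = [box(a.t_start, a.t_end) for a in anns]
        rep = score_run([(boxes, anns)], "automated")
        assert rep.precision == 1.0 and rep.recall == 1.0
        assert rep.precision_iqr == 0.0 and rep.recall_iqr == 0.0
        assert rep.per_type["tsak"]["recall"] == 1.0

    def test_semi_mode_dominates_automated(self):
        rng = np.random.default_rng(4)
        files = []
        for f in range(6):
            anns = [ann(i * 1.0, i * 1.0 + 0.2, aid=f"a{i}") for i in range(8)]
            boxes = []
            for a in anns[:6]:
                jitter = float(rng.uniform(0, 0.15))
                boxes.append(box(a.t_start + jitter, a.t_end))
            boxes.append(box(20.0, 20.1))  # stray noise detection
            files.append((boxes, anns))
        auto = score_run(files, "automated")
        semi = score_run(files, "semi_automated")
        assert semi.precision >= auto.precision
        assert semi.recall >= auto.recall

    def test_mode_and_empty_input_validation(self):
        with pytest.raises(ValueError):
            score_run([], "automated")
        with pytest.raises(ValueError):
            score_run([([], [])], "manual")

    def test_file_without_targets_warns_and_skips_recall(self):
        boxes = [box(0.0, 0.1)]
        with pytest.warns(UserWarning):
            rep = score_run([(boxes, []), ([box(1.0, 1.1)], [ann(1.0, 1.1, aid="a0")])],
                            "automated")
        assert rep.recall_median == 1.0
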