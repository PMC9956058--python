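"""Metric oracles: confusion-count ratios against direct arithmetic, AP
against a brute-force threshold sweep, matching against exhaustive
enumeration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from distilharvest.detnet.boxes import Detection, iou_xywh
from distilharvest.evalkit import (ConfusionCounts, PRCurve, average_precision,
                                   basic_metrics, confusion_matrix,
                                   detection_map, map_over_classes,
                                   match_detections, pr_curve)


class TestBasicMetrics:
    def test_printed_style_counts(self):
        m = basic_metrics(ConfusionCounts(tp=8, fp=2, tn=88, fn=2))
        assert np.isclose(m["precision"], 0.8)
        assert np.isclose(m["recall"], 0.8)
        assert np.isclose(m["accuracy"], 0.96)
        assert np.isclose(m["f1"], 0.8)
        assert np.isclose(m["specificity"], 88 / 90)

    def test_perfect_classifier(self):
        m = basic_metrics(ConfusionCounts(tp=5, fp=0, tn=10, fn=0))
        assert m["precision"] == m["recall"] == m["f1"] == 1.0

    def test_zero_denominator_is_undefined_not_zero(self):
        m = basic_metrics(ConfusionCounts(tp=0, fp=0, tn=3, fn=2))
        assert m["precision"] is None
        assert m["recall"] == 0.0

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            basic_metrics(ConfusionCounts(tp=-1))


class TestMatching:
    def box(self, cx, cy=0.5, w=0.2, h=0.2):
        return (cx, cy, w, h)

    def test_perfect_predictions_all_tp(self):
        truths = [(0, *self.box(0.2)), (0, *self.box(0.7))]
        dets = [Detection(0, 0.9, self.box(0.2)), Detection(0, 0.8, self.box(0.7))]
        assert match_detections(dets, truths) == [True, True]

    def test_duplicate_detection_one_tp_one_fp(self):
        truths = [(0, *self.box(0.5))]
        dets = [Detection(0, 0.9, self.box(0.5)), Detection(0, 0.85, self.box(0.5))]
        assert match_detections(dets, truths) == [True, False]

    def test_three_truths_two_detections_enumerated(self):
        # IoUs 0.6 and 0.4 against distinct truths at threshold 0.5
        truths = [(0, 0.2, 0.5, 0.2, 0.2), (0, 0.5, 0.5, 0.2, 0.2),
                  (0, 0.8, 0.5, 0.2, 0.2)]
        d1 = Detection(0, 0.9, (0.2, 0.5 + 0.05, 0.2, 0.2))   # IoU 0.6 w/ t0
        d2 = Detection(0, 0.8, (0.5 + 0.086, 0.5, 0.2, 0.2))  # IoU ~0.4 w/ t1
        assert iou_xywh(d1.box, truths[0][1:]) > 0.5
        assert iou_xywh(d2.box, truths[1][1:]) < 0.5
        flags = match_detections([d1, d2], truths, 0.5)
        assert flags == [True, False]

    def _best_assignment(self, dets, truths, thr):
        """Exhaustive one-to-one assignment maximizing the TP count."""
        feasible = [[j for j, t in enumerate(truths)
                     if t[0] == d.class_id
                     and iou_xywh(d.box, t[1:5]) >= thr] for d in dets]

        def rec(i, used):
            if i == len(dets):
                return 0
            best = rec(i + 1, used)   # detection i left unmatched
            for j in feasible[i]:
                if j not in used:
                    best = max(best, 1 + rec(i + 1, used | {j}))
            return best

        return rec(0, frozenset())

    def test_never_exceeds_exhaustive_enumeration(self, rng):
        """On random <=5-box instances the greedy one-match rule never counts
        more TPs than the best one-to-one assignment found by brute force."""
        for _ in range(25):
            nt, nd = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            truths = [(0, *rng.uniform(0.2, 0.8, 2), *rng.uniform(0.1, 0.3, 2))
                      for _ in range(nt)]
            dets = [Detection(0, float(rng.random()),
                              (*rng.uniform(0.2, 0.8, 2),
                               *rng.uniform(0.1, 0.3, 2))) for _ in range(nd)]
            greedy_tp = sum(match_detections(dets, truths, 0.3))
            assert greedy_tp <= self._best_assignment(dets, truths, 0.3)

    def test_equals_enumeration_when_overlaps_are_unambiguous(self, rng):
        """With well-separated truths each detection overlaps at most one
        truth, and the greedy rule attains the exhaustive optimum."""
        for _ in range(10):
            centres = [0.15, 0.5, 0.85]
            truths = [(0, c, 0.5, 0.18, 0.18) for c in centres]
            dets = [Detection(0, float(rng.random()),
                              (c + float(rng.uniform(-0.03, 0.03)), 0.5,
                               0.18, 0.18))
                    for c in centres for _ in range(int(rng.integers(0, 3)))]
            greedy_tp = sum(match_detections(dets, truths, 0.5))
            assert greedy_tp == self._best_assignment(dets, truths, 0.5)


class TestAveragePrecision:
    def test_rectangular_curve_area_half(self):
        curve = PRCurve(recall=np.array([0.5, 1.0]),
                        precision=np.array([1.0, 0.0]))
        ap = average_precision(curve, method="trapezoid")
        assert np.isclose(ap, 0.75)  # trapezoid bridges the drop
        # step-style reading of the same curve
        curve2 = PRCurve(recall=np.array([0.25, 0.5, 0.500001, 1.0]),
                         precision=np.array([1.0, 1.0, 0.0, 0.0]))
        assert np.isclose(average_precision(curve2, method="trapezoid"), 0.5,
                          atol=1e-3)

    def test_matches_brute_force_threshold_sweep(self, rng):
        """Oracle: enumerate every score threshold, accumulate trapezoids."""
        for trial in range(10):
            n = int(rng.integers(3, 30))
            scores = rng.random(n)
            is_tp = rng.random(n) > 0.4
            n_truth = int(is_tp.sum() + rng.integers(0, 4))
            if n_truth == 0:
                continue
            curve = pr_curve(scores, is_tp, n_truth)
            ap = average_precision(curve, method="trapezoid")
            # independent sweep: sort unique thresholds descending
            pts = [(0.0, None)]
            rp = []
            for thr in sorted(scores, reverse=True):
                sel = scores >= thr
                tp = (is_tp & sel).sum()
                fp = (~is_tp & sel).sum()
                rp.append((tp / n_truth, tp / (tp + fp)))
            brute = 0.0
            prev_r, prev_p = 0.0, rp[0][1]
            for r, p in rp:
                brute += (r - prev_r) * (p + prev_p) / 2
                prev_r, prev_p = r, p
            assert abs(ap - brute) < 1e-6

    def test_interp101_bounded_and_close_to_trapezoid(self, rng):
        scores = rng.random(50)
        is_tp = rng.random(50) > 0.5
        curve = pr_curve(scores, is_tp, int(is_tp.sum()))
        a1 = average_precision(curve, method="interp101")
        a2 = average_precision(curve, method="trapezoid")
        assert 0 <= a1 <= 1 and abs(a1 - a2) < 0.15


class TestMAP:
    def test_single_class_map_is_ap(self):
        assert map_over_classes([0.7]) == 0.7

    def test_arithmetic_mean(self):
        assert np.isclose(map_over_classes([1.0, 0.5]), 0.75)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            map_over_classes([])

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariant_and_bounded(self, aps):
        m = map_over_classes(aps)
        assert np.isclose(m, map_over_classes(list(reversed(aps))))
        assert min(aps) - 1e-12 <= m <= max(aps) + 1e-12

    def test_detection_map_perfect(self):
        truths = [[(0, 0.3, 0.3, 0.2, 0.2)], [(1, 0.6, 0.6, 0.2, 0.2)]]
        dets = [[Detection(0, 0.9, (0.3, 0.3, 0.2, 0.2))],
                [Detection(1, 0.8, (0.6, 0.6, 0.2, 0.2))]]
        assert detection_map(dets, truths, 2)["mAP"] == 1.0


class TestConfusionMatrix:
    def test_perfect_classifier_identity(self):
        dets = [[Detection(c, 0.9, (0.5, 0.5, 0.2, 0.2))] for c in range(5)]
        cm = confusion_matrix(dets, list(range(5)), 5)
        assert np.allclose(cm[:, :5], np.eye(5))

    def test_rows_sum_to_one(self, rng):
        dets = [[Detection(int(rng.integers(5)), 0.5, (0.5, 0.5, 0.2, 0.2))]
                for _ in range(40)]
        cm = confusion_matrix(dets, list(rng.integers(0, 5, 40)), 5)
        sums = cm.sum(axis=1)
        assert np.allclose(sums[sums > 0], 1.0)

    def test_uniform_random_predictions_near_uniform_rows(self):
        rng = np.random.default_rng(0)
        n = 4000
        dets = [[Detection(int(rng.integers(5)), 0.5, (0.5, 0.5, 0.2, 0.2))]
                for _ in range(n)]
        cm = confusion_matrix(dets, [0] * n, 5)
        sigma = np.sqrt(0.2 * 0.8 / n)
        assert np.abs(cm[0, :5] - 0.2).max() < 3 * sigma + 1e-9

    def test_all_suppressed_goes_to_missed(self):
        cm = confusion_matrix([[], []], [0, 1], 5)
        assert cm[0, 5] == 1.0 and cm[1, 5] == 1.0
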