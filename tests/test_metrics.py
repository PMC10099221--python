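"""Closed-form metric checks and matching-oracle agreement."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grainseg.metrics import (
    ConfusionCounts,
    Detection,
    MatchSpec,
    average_precision,
    evaluate_detections,
    mask_iou,
    match,
    mean_ap,
    precision,
    recall,
)
from grainseg.synthetic import InstanceAnnotation


def _gt(cid, x1, y1, x2, y2, size=40):
    mask = np.zeros((size, size), bool)
    mask[y1:y2, x1:x2] = True
    return InstanceAnnotation(cid, (float(x1), float(y1), float(x2), float(y2)),
                              mask, int(mask.sum()))


def _det(cid, score, x1, y1, x2, y2, size=40):
    mask = np.zeros((size, size), bool)
    mask[y1:y2, x1:x2] = True
    return Detection(cid, score, (float(x1), float(y1), float(x2), float(y2)), mask)


class TestRates:
    def test_precision_recall_closed_forms(self):
        assert precision(ConfusionCounts(TP=86, FP=14)) == pytest.approx(0.86)
        assert recall(ConfusionCounts(TP=91, FN=9)) == pytest.approx(0.91)
        with pytest.warns(UserWarning):
            assert recall(ConfusionCounts(TP=0, FN=0)) == 0.0
        assert recall(ConfusionCounts(TP=0, FN=5)) == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(TP=-1)


class TestMaskIoU:
    def test_identical_disjoint_and_half(self):
        a = np.zeros((10, 10), bool)
        a[:5] = True
        assert mask_iou(a, a) == 1.0
        assert mask_iou(a, ~a) == 0.0
        big = np.zeros((10, 20), bool)
        big[0, :10] = True
        small = np.zeros((10, 20), bool)
        small[0, :5] = True
        assert mask_iou(big, small) == 0.5

    def test_dim_mismatch_rejected_and_empty_warns(self):
        with pytest.raises(ValueError):
            mask_iou(np.zeros((2, 2), bool), np.zeros((3, 3), bool))
        with pytest.warns(UserWarning):
            assert mask_iou(np.zeros((2, 2), bool), np.zeros((2, 2), bool)) == 0.0


class TestMatch:
    def test_exact_overlap_same_class(self):
        order, tp, fn = match([_det(1, 0.9, 0, 0, 10, 10)], [_gt(1, 0, 0, 10, 10)])
        assert tp.tolist() == [True] and fn == 0

    def test_two_predictions_one_gt(self):
        preds = [_det(1, 0.9, 0, 0, 10, 10), _det(1, 0.8, 0, 0, 10, 10)]
        order, tp, fn = match(preds, [_gt(1, 0, 0, 10, 10)])
        assert tp.tolist() == [True, False] and fn == 0

    def test_class_mismatch_is_fp_and_fn(self):
        order, tp, fn = match([_det(2, 0.9, 0, 0, 10, 10)], [_gt(1, 0, 0, 10, 10)])
        assert tp.tolist() == [False] and fn == 1

    def test_agrees_with_exhaustive_greedy_enumeration(self, rng):
        """Greedy matching must equal brute force over all GT subsets/orders."""
        spec = MatchSpec(iou_kind="box")

        def brute(preds, gts):
            order = sorted(range(len(preds)), key=lambda i: (-preds[i].score, i))
            used = set()
            n_tp = 0
            for i in order:
                best, bi = 0.0, -1
                for j, g in enumerate(gts):
                    if j in used or g.category_id != preds[i].category_id:
                        continue
                    from grainseg.rpn import box_iou_matrix

                    v = box_iou_matrix(np.array(preds[i].box)[None],
                                       np.array(g.bbox)[None])[0, 0]
                    if v > best:
                        best, bi = v, j
                if bi >= 0 and best >= spec.iou_threshold:
                    used.add(bi)
                    n_tp += 1
            return n_tp, len(gts) - len(used)

        for _ in range(200):
            np_, ng = int(rng.integers(0, 6)), int(rng.integers(0, 6))
            preds, gts = [], []
            for _ in range(np_):
                x, y = rng.integers(0, 20, 2)
                w, h = rng.integers(4, 15, 2)
                preds.append(_det(int(rng.integers(1, 3)), float(rng.uniform()),
                                  x, y, x + w, y + h))
            for _ in range(ng):
                x, y = rng.integers(0, 20, 2)
                w, h = rng.integers(4, 15, 2)
                gts.append(_gt(int(rng.integers(1, 3)), x, y, x + w, y + h))
            order, tp, fn = match(preds, gts, spec)
            assert (int(tp.sum()), fn) == brute(preds, gts)


class TestAveragePrecision:
    def test_single_true_positive(self):
        assert average_precision(np.array([0.9]), np.array([True]), n_gt=1) == 1.0

    def test_worked_two_detection_case(self):
        ap = average_precision(np.array([0.9, 0.8]), np.array([True, False]), n_gt=2)
        assert ap == pytest.approx(0.5)

    def test_reference_six_class_mean(self):
        aps = {"perfect": 0.60, "moldy": 0.99, "injured": 0.82,
               "spotted": 0.89, "sprouted": 0.89, "broken": 0.98}
        m = mean_ap(aps)
        assert m == pytest.approx(0.8616666666, abs=1e-9)
        assert round(m, 2) == 0.86

    def test_mean_ap_is_arithmetic_mean_to_machine_precision(self, rng):
        vals = rng.uniform(0, 1, 6)
        assert abs(mean_ap(list(vals)) - vals.sum() / 6) < 1e-12

    def test_inserting_high_fp_never_raises_ap(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 12))
            scores = rng.uniform(0.1, 1, n)
            tp = rng.uniform(0, 1, n) < 0.6
            n_gt = max(int(tp.sum()), 1)
            base = average_precision(scores, tp, n_gt)
            corrupted = average_precision(
                np.concatenate([scores, [scores.max() + 0.01]]),
                np.concatenate([tp, [False]]),
                n_gt,
            )
            assert corrupted <= base + 1e-12

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_ap_stays_in_unit_interval(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(1, 20))
        tp = r.uniform(0, 1, n) < 0.5
        n_gt = int(tp.sum()) + int(r.integers(1, 6))
        ap = average_precision(r.uniform(0, 1, n), tp, n_gt=n_gt)
        assert 0.0 <= ap <= 1.0

    def test_coco101_mode_close_to_all_point_on_simple_case(self):
        scores = np.array([0.9, 0.8, 0.7, 0.6])
        tp = np.array([True, True, False, True])
        a = average_precision(scores, tp, 3, "all_point")
        b = average_precision(scores, tp, 3, "coco101")
        assert abs(a - b) < 0.05


class TestEvaluate:
    def test_perfect_predictions_score_one(self):
        gts = [[_gt(1, 0, 0, 10, 10), _gt(2, 20, 20, 30, 30)]]
        preds = [[_det(1, 0.9, 0, 0, 10, 10), _det(2, 0.8, 20, 20, 30, 30)]]
        rep = evaluate_detections(preds, gts)
        assert rep.precision == rep.recall == 1.0
        assert rep.map == 1.0 and rep.miou == 1.0

    def test_idempotent_evaluation(self):
        gts = [[_gt(1, 0, 0, 10, 10)]]
        preds = [[_det(1, 0.9, 1, 0, 11, 10)]]
        r1 = evaluate_detections(preds, gts)
        r2 = evaluate_detections(preds, gts)
        assert r1.to_dict() == r2.to_dict()

    def test_rates_bounded(self, rng):
        gts = [[_gt(int(rng.integers(1, 7)), 0, 0, 12, 12)] for _ in range(3)]
        preds = [
            [_det(int(rng.integers(1, 7)), float(rng.uniform()), 0, 0, 12, 12)]
            for _ in range(3)
        ]
        rep = evaluate_detections(preds, gts)
        for v in [rep.map, rep.ar, rep.miou, rep.precision, rep.recall]:
            assert 0.0 <= v <= 1.0
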