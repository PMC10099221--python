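"""Anchors, IoU, NMS, fg/bg assignment, delta coding, proposal filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grainseg.rpn import (
    BG,
    DISCARD,
    FG,
    AnchorConfig,
    AssignmentConfig,
    RPNHead,
    anchor_shape,
    assign_fg_bg,
    decode_deltas,
    encode_deltas,
    generate_anchors,
    iou,
    nms,
    propose,
)


# -- independent oracles ----------------------------------------------------

def _iou_scalar(a, b):
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    u = area_a + area_b - inter
    return inter / u if u > 0 else 0.0


def brute_force_nms(boxes, scores, thr):
    order = sorted(range(len(boxes)), key=lambda i: (-scores[i], i))
    kept = []
    for i in order:
        if all(_iou_scalar(boxes[i], boxes[j]) <= thr for j in kept):
            kept.append(i)
    return kept


def raster_iou(a, b, size=80):
    """Pixel-count IoU oracle for integer-coordinate boxes."""
    ga = np.zeros((size, size), bool)
    gb = np.zeros((size, size), bool)
    ga[a[1]:a[3], a[0]:a[2]] = True
    gb[b[1]:b[3], b[0]:b[2]] = True
    union = (ga | gb).sum()
    return (ga & gb).sum() / union if union else 0.0


# -- anchors ----------------------------------------------------------------

class TestAnchors:
    def test_square_and_rectangular_shapes(self):
        assert anchor_shape(8, 1.0) == (8.0, 8.0)
        w, h = anchor_shape(8, 2.0)
        assert w == pytest.approx(8 / np.sqrt(2))
        assert h == pytest.approx(8 * np.sqrt(2))
        assert w * h == pytest.approx(64.0)

    def test_count_formula_per_level(self):
        cfg = AnchorConfig()
        dims = {k: (2 ** (8 - k), 2 ** (8 - k)) for k in range(2, 7)}
        strides = {k: 2**k for k in range(2, 7)}
        anchors = generate_anchors(dims, strides, cfg)
        for k, (h, w) in dims.items():
            assert len(anchors[k]) == h * w * cfg.anchors_per_cell(k)
        # six scales, three ratios, one-per-level except the finest
        assert cfg.anchors_per_cell(2) == 6
        assert all(cfg.anchors_per_cell(k) == 3 for k in range(3, 7))

    def test_single_cell_centering(self):
        cfg = AnchorConfig.single_level(2)
        anchors = generate_anchors({2: (1, 1)}, {2: 4}, cfg)[2]
        assert len(anchors) == 18
        centers = (anchors[:, :2] + anchors[:, 2:]) / 2
        assert np.allclose(centers, 2.0)

    def test_small_grid_count(self):
        cfg = AnchorConfig(scales=(8,), level_assignment={2: (8,)})
        anchors = generate_anchors({2: (4, 4)}, {2: 4}, cfg)[2]
        assert len(anchors) == 48

    def test_every_scale_assigned_exactly_once(self):
        with pytest.raises(ValueError):
            AnchorConfig(level_assignment={2: (8, 8, 16), 3: (32, 64, 128, 256)})

    def test_empty_assignment_rejected(self):
        with pytest.raises(ValueError, match="no anchor scales"):
            generate_anchors({7: (2, 2)}, {7: 128}, AnchorConfig())


# -- IoU ---------------------------------------------------------------------

class TestIoU:
    def test_identity_disjoint_and_known_fraction(self):
        assert iou((0, 0, 10, 10), (0, 0, 10, 10)) == 1.0
        assert iou((0, 0, 10, 10), (20, 20, 30, 30)) == 0.0
        assert iou((0, 0, 10, 10), (5, 0, 15, 10)) == pytest.approx(1 / 3)

    def test_degenerate_box_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert iou((0, 0, 0, 10), (0, 0, 10, 10)) == 0.0

    def test_matches_rasterized_pixel_count_oracle(self, rng):
        for _ in range(300):
            ax = np.sort(rng.integers(0, 60, 2))
            ay = np.sort(rng.integers(0, 60, 2))
            bx = np.sort(rng.integers(0, 60, 2))
            by = np.sort(rng.integers(0, 60, 2))
            a = (ax[0], ay[0], ax[1] + 1, ay[1] + 1)
            b = (bx[0], by[0], bx[1] + 1, by[1] + 1)
            assert iou(a, b) == pytest.approx(raster_iou(a, b), abs=1e-9)


# -- NMS ----------------------------------------------------------------------

class TestNMS:
    def test_worked_example(self):
        boxes = np.array([(0, 0, 10, 10), (1, 1, 11, 11), (20, 20, 30, 30)], float)
        scores = np.array([0.9, 0.8, 0.7])
        assert nms(boxes, scores, 0.5).tolist() == [0, 2]

    def test_trivial_cases(self):
        assert nms(np.array([[0, 0, 5, 5]]), np.array([1.0]), 0.5).tolist() == [0]
        boxes = np.array([(0, 0, 5, 5), (10, 10, 15, 15)], float)
        assert sorted(nms(boxes, np.array([0.2, 0.9]), 0.01).tolist()) == [0, 1]
        assert nms(np.empty((0, 4)), np.empty(0), 0.5).size == 0

    def test_agrees_with_brute_force_on_random_instances(self, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 51))
            xy = rng.uniform(0, 40, (n, 2))
            wh = rng.uniform(1, 25, (n, 2))
            boxes = np.concatenate([xy, xy + wh], axis=1)
            scores = np.round(rng.uniform(0, 1, n), 3)  # rounding forces ties
            thr = float(rng.uniform(0.2, 0.7))
            assert nms(boxes, scores, thr).tolist() == brute_force_nms(boxes, scores, thr)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_lowering_threshold_never_keeps_more(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(1, 30))
        xy = r.uniform(0, 30, (n, 2))
        boxes = np.concatenate([xy, xy + r.uniform(1, 20, (n, 2))], axis=1)
        scores = r.uniform(0, 1, n)
        lo, hi = sorted(r.uniform(0.1, 0.9, 2))
        assert len(nms(boxes, scores, lo)) <= len(nms(boxes, scores, hi))


# -- assignment ----------------------------------------------------------------

class TestAssignment:
    def test_threshold_bands(self):
        gt = np.array([[0, 0, 10, 10]], float)
        anchors = np.array(
            [
                [0, 0, 10, 10],      # IoU 1.00 -> fg
                [0, 0, 10, 13.4],    # IoU ~0.75 -> fg
                [0, 0, 10, 20],      # IoU 0.50 -> discard
                [8, 8, 18, 18],      # IoU small -> bg
                [40, 40, 50, 50],    # IoU 0 -> bg
            ]
        )
        labels = assign_fg_bg(anchors, gt, AssignmentConfig(), rescue=False)
        assert labels.tolist() == [FG, FG, DISCARD, BG, BG]

    def test_partition_covers_all_anchors(self, rng):
        anchors = rng.uniform(0, 50, (200, 2))
        anchors = np.concatenate([anchors, anchors + rng.uniform(2, 20, (200, 2))], axis=1)
        gt = np.array([[5, 5, 25, 25], [30, 30, 45, 45]], float)
        labels = assign_fg_bg(anchors, gt)
        assert set(labels.tolist()) <= {FG, BG, DISCARD}
        assert len(labels) == 200

    def test_rescue_rule_gives_every_gt_a_foreground_anchor(self):
        gt = np.array([[0, 0, 9, 9]], float)
        anchors = np.array([[0, 0, 9, 14], [100, 100, 110, 110]], float)  # best IoU ~0.64
        labels = assign_fg_bg(anchors, gt, rescue=True)
        assert labels[0] == FG
        labels_no = assign_fg_bg(anchors, gt, rescue=False)
        assert labels_no[0] == DISCARD

    def test_no_ground_truth_means_all_background(self):
        anchors = np.array([[0, 0, 5, 5], [3, 3, 8, 8]], float)
        assert assign_fg_bg(anchors, np.empty((0, 4))).tolist() == [BG, BG]


# -- delta coding and proposals -------------------------------------------------

class TestDeltas:
    def test_zero_deltas_decode_to_anchors(self, rng):
        anchors = np.array([[2, 3, 10, 9], [0, 0, 16, 8]], float)
        assert np.allclose(decode_deltas(anchors, np.zeros((2, 4))), anchors)

    def test_log_width_delta_doubles_width(self):
        anchors = np.array([[0, 0, 10, 10]], float)
        out = decode_deltas(anchors, np.array([[0, 0, np.log(2), 0]]))
        assert out[0, 2] - out[0, 0] == pytest.approx(20.0)
        assert out[0, 3] - out[0, 1] == pytest.approx(10.0)

    def test_encode_decode_round_trip(self, rng):
        anchors = np.concatenate([rng.uniform(0, 20, (30, 2)),
                                  rng.uniform(30, 60, (30, 2))], axis=1)
        boxes = np.concatenate([rng.uniform(0, 20, (30, 2)),
                                rng.uniform(30, 60, (30, 2))], axis=1)
        deltas = encode_deltas(anchors, boxes)
        assert np.allclose(decode_deltas(anchors, deltas), boxes, atol=1e-8)


class TestPropose:
    def _setup(self):
        cfg = AnchorConfig(scales=(8,), level_assignment={2: (8,)})
        anchors = generate_anchors({2: (4, 4)}, {2: 4}, cfg)
        return anchors

    def test_zero_deltas_return_clipped_anchors(self):
        anchors = self._setup()
        n = len(anchors[2])
        scores = {2: np.linspace(1, 0, n)}
        deltas = {2: np.zeros((n, 4))}
        out = propose(scores, deltas, anchors, (16, 16),
                      AssignmentConfig(nms_iou=0.99, pre_nms_topk=n, post_nms_topk=n))
        assert len(out.boxes) > 0
        assert (out.boxes[:, 0] >= 0).all() and (out.boxes[:, 2] <= 16).all()
        assert (np.diff(out.objectness) <= 1e-12).all()  # sorted descending

    def test_post_nms_topk_one_keeps_single_best(self):
        anchors = self._setup()
        n = len(anchors[2])
        rng = np.random.default_rng(0)
        scores = {2: rng.uniform(0, 1, n)}
        deltas = {2: np.zeros((n, 4))}
        out = propose(scores, deltas, anchors, (16, 16),
                      AssignmentConfig(post_nms_topk=1))
        assert len(out.boxes) == 1
        assert out.objectness[0] == scores[2].max()

    def test_shape_mismatch_rejected(self):
        anchors = self._setup()
        with pytest.raises(ValueError, match="anchors"):
            propose({2: np.zeros(3)}, {2: np.zeros((3, 4))}, anchors, (16, 16))


class TestRPNHead:
    def test_output_shapes_follow_anchor_counts(self, rng):
        from grainseg import nn
        from grainseg.nn.tensor import Tensor

        nn.seed(0)
        head = RPNHead(width=8, max_anchors_per_cell=6)
        x = Tensor(rng.normal(size=(1, 8, 5, 7)).astype(np.float32))
        obj, deltas = head(x, anchors_per_cell=3)
        assert obj.shape == (1, 5 * 7 * 3)
        assert deltas.shape == (1, 5 * 7 * 3, 4)
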