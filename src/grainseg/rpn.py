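"""Region-proposal stage: anchors, IoU, NMS, fg/bg assignment, decoding.

Anchor design follows the dense-small-target setup: six scale options
{8, 16, 32, 64, 128, 256} at three aspect ratios {0.5, 1, 2}, distributed
over the pyramid levels (the finest level carries two scales so the six
scales fit five levels).  Foreground/background assignment uses the
0.7 / 0.3 IoU screening thresholds, and proposal NMS runs at 0.5 — a
deliberately low threshold so two adherent kernels are not merged into a
single proposal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn

__all__ = [
    "AnchorConfig",
    "AssignmentConfig",
    "ProposalSet",
    "generate_anchors",
    "anchor_shape",
    "iou",
    "box_iou_matrix",
    "nms",
    "assign_fg_bg",
    "decode_deltas",
    "encode_deltas",
    "propose",
    "RPNHead",
    "FG", "BG", "DISCARD",
]

FG, BG, DISCARD = 1, 0, -1

_DEFAULT_SCALES = (8, 16, 32, 64, 128, 256)


def _default_assignment(levels: int = 5) -> dict[int, tuple[int, ...]]:
    """Six scales over five pyramid levels: the finest level takes {8, 16}."""
    return {2: (8, 16), 3: (32,), 4: (64,), 5: (128,), 6: (256,)}


@dataclass(frozen=True)
class AnchorConfig:
    scales: tuple[int, ...] = _DEFAULT_SCALES
    ratios: tuple[float, ...] = (0.5, 1.0, 2.0)
    level_assignment: dict[int, tuple[int, ...]] = field(default_factory=_default_assignment)

    def __post_init__(self):
        assigned = [s for sc in self.level_assignment.values() for s in sc]
        if sorted(assigned) != sorted(self.scales):
            raise ValueError(
                f"level_assignment {self.level_assignment} must use every scale in "
                f"{self.scales} exactly once"
            )

    @staticmethod
    def single_level(level: int = 2) -> "AnchorConfig":
        """All six scales on one level (the single-feature-map reading)."""
        return AnchorConfig(level_assignment={level: _DEFAULT_SCALES})

    def anchors_per_cell(self, level: int) -> int:
        return len(self.level_assignment.get(level, ())) * len(self.ratios)


@dataclass(frozen=True)
class AssignmentConfig:
    fg_iou: float = 0.7
    bg_iou: float = 0.3
    nms_iou: float = 0.5
    pre_nms_topk: int = 2000
    post_nms_topk: int = 1000

    def __post_init__(self):
        if not (0.0 <= self.bg_iou < self.fg_iou <= 1.0):
            raise ValueError("need 0 <= bg_iou < fg_iou <= 1")
        if not (0.0 < self.nms_iou < 1.0):
            raise ValueError("need 0 < nms_iou < 1")


@dataclass
class ProposalSet:
    boxes: np.ndarray  # (M, 4) x1y1x2y2, sorted by descending objectness
    objectness: np.ndarray  # (M,)
    source_level: np.ndarray  # (M,) int level index


def anchor_shape(scale: float, ratio: float) -> tuple[float, float]:
    """(width, height) with area scale² and height/width = ratio."""
    w = scale / np.sqrt(ratio)
    return float(w), float(w * ratio)


def generate_anchors(level_dims: dict[int, tuple[int, int]], strides: dict[int, int],
                     config: AnchorConfig = AnchorConfig()) -> dict[int, np.ndarray]:
    """Tile anchors at every cell center of every assigned level.

    Returns level -> (h*w*A, 4) float boxes in input-image coordinates,
    ordered row-major over cells, then (scale, ratio) per cell.
    """
    out: dict[int, np.ndarray] = {}
    for level, (h, w) in level_dims.items():
        scales = config.level_assignment.get(level, ())
        if not scales:
            raise ValueError(f"no anchor scales assigned to level {level}")
        s = strides[level]
        shapes = np.array(
            [anchor_shape(sc, r) for sc in scales for r in config.ratios]
        )  # (A, 2) w,h
        cy, cx = np.mgrid[0:h, 0:w].astype(np.float64)
        cx = (cx + 0.5) * s
        cy = (cy + 0.5) * s
        centers = np.stack([cx, cy], axis=-1).reshape(h * w, 1, 2)
        half = shapes[None, :, :] / 2.0
        boxes = np.concatenate([centers - half, centers + half], axis=-1)
        out[level] = boxes.reshape(-1, 4)
    return out


def _areas(boxes: np.ndarray) -> np.ndarray:
    return np.maximum(boxes[:, 2] - boxes[:, 0], 0) * np.maximum(boxes[:, 3] - boxes[:, 1], 0)


def box_iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(M, N) IoU matrix of two box arrays (x1y1x2y2)."""
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(br - tl, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    union = _areas(a)[:, None] + _areas(b)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return out


def iou(box_a, box_b) -> float:
    """Intersection-over-union of two boxes; 0 (with warning) if degenerate."""
    a = np.asarray(box_a, dtype=np.float64)
    b = np.asarray(box_b, dtype=np.float64)
    if _areas(a[None])[0] <= 0 or _areas(b[None])[0] <= 0:
        warnings.warn("IoU of a degenerate (zero-area) box is defined as 0")
        return 0.0
    return float(box_iou_matrix(a[None], b[None])[0, 0])


def nms(boxes: np.ndarray, scores: np.ndarray, nms_iou: float) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices.

    Boxes are visited in descending score order (ties broken by lower
    original index) and suppressed iff IoU with an already-kept box is
    strictly greater than ``nms_iou``.
    """
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    scores = np.asarray(scores, dtype=np.float64).ravel()
    if len(boxes) != len(scores):
        raise ValueError("boxes and scores must have equal length")
    if len(boxes) == 0:
        return np.empty(0, dtype=np.int64)
    order = np.argsort(-scores, kind="stable")
    b = boxes[order]
    areas = _areas(b)
    alive = np.ones(len(b), dtype=bool)
    keep: list[int] = []
    for pos in range(len(b)):
        if not alive[pos]:
            continue
        keep.append(int(order[pos]))
        rest = alive[pos + 1 :]
        if not rest.any():
            continue
        cand = b[pos + 1 :]
        tl = np.maximum(b[pos, :2], cand[:, :2])
        br = np.minimum(b[pos, 2:], cand[:, 2:])
        wh = np.clip(br - tl, 0, None)
        inter = wh[:, 0] * wh[:, 1]
        union = areas[pos] + areas[pos + 1 :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            ious = np.where(union > 0, inter / union, 0.0)
        alive[pos + 1 :] &= ious <= nms_iou
    return np.asarray(keep, dtype=np.int64)


def assign_fg_bg(anchors: np.ndarray, gt_boxes: np.ndarray,
                 config: AssignmentConfig = AssignmentConfig(),
                 rescue: bool = True) -> np.ndarray:
    """Label each anchor foreground (1), background (0), or discard (-1).

    Screening is by max IoU over ground truths: above ``fg_iou`` is
    foreground, below ``bg_iou`` background, in between discarded.  With
    ``rescue`` (default), the best-overlapping anchor of every ground truth
    is additionally foreground so no target goes unmatched.
    """
    anchors = np.asarray(anchors, dtype=np.float64).reshape(-1, 4)
    gt_boxes = np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4)
    if len(gt_boxes) == 0:
        return np.zeros(len(anchors), dtype=np.int64)
    m = box_iou_matrix(anchors, gt_boxes)  # (A, G)
    best = m.max(axis=1)
    labels = np.full(len(anchors), DISCARD, dtype=np.int64)
    labels[best < config.bg_iou] = BG
    labels[best > config.fg_iou] = FG
    if rescue:
        gt_best = m.max(axis=0)  # (G,)
        for g in range(len(gt_boxes)):
            if gt_best[g] > 0:
                labels[m[:, g] >= gt_best[g] - 1e-9] = FG
    return labels


def encode_deltas(anchors: np.ndarray, boxes: np.ndarray) -> np.ndarray:
    """Regression targets (dx, dy, dw, dh) mapping anchors onto boxes."""
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    ax = anchors[:, 0] + 0.5 * aw
    ay = anchors[:, 1] + 0.5 * ah
    bw = boxes[:, 2] - boxes[:, 0]
    bh = boxes[:, 3] - boxes[:, 1]
    bx = boxes[:, 0] + 0.5 * bw
    by = boxes[:, 1] + 0.5 * bh
    return np.stack(
        [(bx - ax) / aw, (by - ay) / ah, np.log(bw / aw), np.log(bh / ah)], axis=1
    )


def decode_deltas(anchors: np.ndarray, deltas: np.ndarray,
                  clip_exp: float = 4.0) -> np.ndarray:
    """Invert :func:`encode_deltas`; zero deltas return the anchors."""
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    ax = anchors[:, 0] + 0.5 * aw
    ay = anchors[:, 1] + 0.5 * ah
    dx, dy, dw, dh = deltas[:, 0], deltas[:, 1], deltas[:, 2], deltas[:, 3]
    cx = ax + dx * aw
    cy = ay + dy * ah
    w = aw * np.exp(np.clip(dw, -clip_exp, clip_exp))
    h = ah * np.exp(np.clip(dh, -clip_exp, clip_exp))
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)


def clip_boxes(boxes: np.ndarray, image_size: tuple[int, int]) -> np.ndarray:
    H, W = image_size
    out = boxes.copy()
    out[:, 0::2] = np.clip(out[:, 0::2], 0, W)
    out[:, 1::2] = np.clip(out[:, 1::2], 0, H)
    return out


def propose(objectness: dict[int, np.ndarray], deltas: dict[int, np.ndarray],
            anchors: dict[int, np.ndarray], image_size: tuple[int, int],
            config: AssignmentConfig = AssignmentConfig(),
            min_size: float = 1.0) -> ProposalSet:
    """Decode per-level RPN outputs into a scored, NMS-filtered proposal set.

    ``objectness[level]`` is a flat (h*w*A,) score array and ``deltas[level]``
    the matching (h*w*A, 4) regression output, both in the anchor ordering of
    :func:`generate_anchors`.
    """
    all_boxes, all_scores, all_levels = [], [], []
    for level, anc in anchors.items():
        sc = np.asarray(objectness[level], dtype=np.float64).ravel()
        dl = np.asarray(deltas[level], dtype=np.float64).reshape(-1, 4)
        if len(sc) != len(anc) or len(dl) != len(anc):
            raise ValueError(
                f"level {level}: got {len(sc)} scores / {len(dl)} deltas for {len(anc)} anchors"
            )
        if len(sc) > config.pre_nms_topk:
            top = np.argpartition(-sc, config.pre_nms_topk)[: config.pre_nms_topk]
            sc, dl, anc = sc[top], dl[top], anc[top]
        boxes = clip_boxes(decode_deltas(anc, dl), image_size)
        wh = np.minimum(boxes[:, 2] - boxes[:, 0], boxes[:, 3] - boxes[:, 1])
        ok = wh >= min_size
        all_boxes.append(boxes[ok])
        all_scores.append(sc[ok])
        all_levels.append(np.full(int(ok.sum()), level, dtype=np.int64))
    boxes = np.concatenate(all_boxes)
    scores = np.concatenate(all_scores)
    levels = np.concatenate(all_levels)
    keep = nms(boxes, scores, config.nms_iou)[: config.post_nms_topk]
    order = keep[np.argsort(-scores[keep], kind="stable")]
    return ProposalSet(boxes=boxes[order], objectness=scores[order], source_level=levels[order])


class RPNHead(nn.Module):
    """Shared sliding-window head: 3×3 conv + ReLU, then 1×1 objectness and
    1×1 box-delta convolutions sized for the largest per-cell anchor count."""

    def __init__(self, width: int, max_anchors_per_cell: int):
        super().__init__()
        self.A = max_anchors_per_cell
        self.conv = nn.Conv2d(width, width, 3, padding=1)
        self.obj = nn.Conv2d(width, self.A, 1, init_gain=0.01)
        self.delta = nn.Conv2d(width, 4 * self.A, 1, init_gain=0.01)

    def forward(self, feat, anchors_per_cell: int):
        """Returns flat objectness logits (N, h*w*A) and deltas (N, h*w*A, 4)
        for the first ``anchors_per_cell`` anchors of each cell, matching the
        anchor ordering of :func:`generate_anchors`."""
        N, _, h, w = feat.shape
        hidden = self.conv(feat).relu()
        A = anchors_per_cell
        obj = self.obj(hidden)[:, :A].transpose(0, 2, 3, 1).reshape(N, h * w * A)
        dl = (
            self.delta(hidden)
            .reshape(N, self.A, 4, h, w)[:, :A]
            .transpose(0, 3, 4, 1, 2)
            .reshape(N, h * w * A, 4)
        )
        return obj, dl
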