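"""The kernel detector: backbone + attention + pyramid + RPN + ROI heads.

A Mask R-CNN-style two-stage instance segmenter.  A residual backbone
produces C2..C5; optional channel attention re-weights each stage output;
a feature pyramid (top-down, bottom-up-fused, or recursive) produces the
prediction levels; a shared RPN head scores anchors and regresses proposal
boxes; ROI-aligned features feed a box head (classification + class-
agnostic box regression) and a 28×28 mask head.  Training uses the
standard five-component multi-task loss.
"""

from __future__ import annotations

import dataclasses
import math
import time
from dataclasses import dataclass

import numpy as np

from . import nn
from .attention import attach_attention
from .config import ModelConfig
from .metrics import Detection
from .nn import functional as F
from .nn.tensor import Tensor
from .pyramid import FeaturePyramid
from .rpn import (
    AssignmentConfig,
    RPNHead,
    assign_fg_bg,
    box_iou_matrix,
    clip_boxes,
    decode_deltas,
    encode_deltas,
    generate_anchors,
    nms,
    propose,
)
from .synthetic import InstanceAnnotation

__all__ = [
    "Backbone",
    "MaskRCNN",
    "DetectionResult",
    "build_model",
    "count_parameters",
    "train_step",
    "fit",
    "normalize_image",
]

_PIXEL_MEAN, _PIXEL_STD = 0.5, 0.25

# second-stage box regression target scaling (the canonical 10/10/5/5 weights)
_BOX_REG_WEIGHTS = np.array([10.0, 10.0, 5.0, 5.0])


def normalize_image(image: np.ndarray) -> Tensor:
    """uint8 RGB (H, W, 3) -> normalized float tensor (1, 3, H, W)."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB (H, W, 3) image, got shape {image.shape}")
    x = image.astype(np.float32) / 255.0
    x = (x - _PIXEL_MEAN) / _PIXEL_STD
    return Tensor(x.transpose(2, 0, 1)[None])


class _BasicBlock(nn.Module):
    def __init__(self, cin, cout, stride, groups=4):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, stride=stride, padding=1, bias=False)
        self.gn1 = nn.GroupNorm(groups, cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, padding=1, bias=False)
        self.gn2 = nn.GroupNorm(groups, cout)
        if stride != 1 or cin != cout:
            self.proj = nn.Conv2d(cin, cout, 1, stride=stride, bias=False)
        else:
            self.proj = nn.Identity()

    def forward(self, x):
        h = self.gn1(self.conv1(x)).relu()
        h = self.gn2(self.conv2(h))
        return (h + self.proj(x)).relu()


class Backbone(nn.Module):
    """Residual backbone producing C2..C5 at strides 4/8/16/32.

    Group-normalized so that training works at batch size 1-4.  Attention
    blocks, when attached, are applied to each stage output before the
    pyramid's lateral connections.
    """

    def __init__(self, widths=(32, 64, 128, 256), blocks=(2, 2, 2, 2), groups=4):
        super().__init__()
        w2 = widths[0]
        self.stem = nn.Sequential(
            nn.Conv2d(3, w2, 3, stride=2, padding=1, bias=False),
            nn.GroupNorm(groups, w2),
            nn.ReLU(),
            nn.Conv2d(w2, w2, 3, stride=2, padding=1, bias=False),
            nn.GroupNorm(groups, w2),
            nn.ReLU(),
        )
        self.stage_channels = {f"C{i + 2}": w for i, w in enumerate(widths)}
        stages = []
        cin = w2
        for i, (w, n) in enumerate(zip(widths, blocks)):
            stride = 1 if i == 0 else 2
            mods = [_BasicBlock(cin, w, stride, groups)]
            mods += [_BasicBlock(w, w, 1, groups) for _ in range(n - 1)]
            stages.append(nn.Sequential(*mods))
            cin = w
        self.stages = nn.ModuleList(stages)
        self.attention = None  # set by attach_attention

    def forward(self, x: Tensor) -> dict[str, Tensor]:
        h = self.stem(x)
        feats = {}
        for i, stage in enumerate(self.stages):
            h = stage(h)
            out = h
            if self.attention is not None:
                out = self.attention[f"C{i + 2}"](out)
            feats[f"C{i + 2}"] = out
        return feats


class BoxHead(nn.Module):
    """Two-layer MLP over ROI features -> class logits + class-agnostic deltas."""

    def __init__(self, width, roi_size, hidden, num_classes):
        super().__init__()
        self.fc1 = nn.Linear(width * roi_size * roi_size, hidden)
        self.fc2 = nn.Linear(hidden, hidden)
        self.cls = nn.Linear(hidden, num_classes + 1, init_gain=0.02)
        self.reg = nn.Linear(hidden, 4, init_gain=0.02)

    def forward(self, roi_feats: Tensor):
        R = roi_feats.shape[0]
        h = self.fc1(roi_feats.reshape(R, -1)).relu()
        h = self.fc2(h).relu()
        return self.cls(h), self.reg(h)


class MaskHead(nn.Module):
    """Small FCN over 14×14 ROI features -> per-class 28×28 mask logits."""

    def __init__(self, width, num_classes):
        super().__init__()
        self.conv1 = nn.Conv2d(width, width, 3, padding=1)
        self.conv2 = nn.Conv2d(width, width, 3, padding=1)
        self.conv3 = nn.Conv2d(width, width, 3, padding=1)
        self.out = nn.Conv2d(width, num_classes, 1, init_gain=0.02)

    def forward(self, roi_feats: Tensor) -> Tensor:
        h = self.conv1(roi_feats).relu()
        h = self.conv2(h).relu()
        h = F.upsample_nearest2(h)  # 14 -> 28
        h = self.conv3(h).relu()
        return self.out(h)


@dataclass
class DetectionResult:
    boxes: np.ndarray  # (M, 4)
    labels: np.ndarray  # (M,) category ids 1..6
    scores: np.ndarray  # (M,)
    masks: np.ndarray  # (M, H, W) bool

    def __len__(self):
        return len(self.labels)

    def to_detections(self) -> list[Detection]:
        return [
            Detection(int(l), float(s), tuple(b), m)
            for b, l, s, m in zip(self.boxes, self.labels, self.scores, self.masks)
        ]


def _roi_level(boxes: np.ndarray) -> np.ndarray:
    """FPN level assignment by box scale (k0=4 at canonical size 224)."""
    areas = np.maximum(boxes[:, 2] - boxes[:, 0], 1e-3) * np.maximum(
        boxes[:, 3] - boxes[:, 1], 1e-3
    )
    k = np.floor(4 + np.log2(np.sqrt(areas) / 224.0 + 1e-8))
    return np.clip(k, 2, 5).astype(np.int64)


def roi_align(feats: dict[int, Tensor], strides: dict[int, int], boxes: np.ndarray,
              out_size: int) -> Tensor:
    """ROI align (one bilinear sample per output cell) over pyramid levels.

    Returns (R, C, out_size, out_size) with rows in the order of ``boxes``.
    """
    R = len(boxes)
    levels = _roi_level(boxes)
    pieces, owners = [], []
    for lv in np.unique(levels):
        idx = np.flatnonzero(levels == lv)
        b = boxes[idx]
        s = strides[int(lv)]
        cell = np.arange(out_size) + 0.5
        w = (b[:, 2] - b[:, 0])[:, None] / out_size
        h = (b[:, 3] - b[:, 1])[:, None] / out_size
        xs = (b[:, 0][:, None] + cell[None, :] * w) / s - 0.5  # (R_g, out)
        ys = (b[:, 1][:, None] + cell[None, :] * h) / s - 0.5
        grid_y = np.repeat(ys[:, :, None], out_size, axis=2)
        grid_x = np.repeat(xs[:, None, :], out_size, axis=1)
        sampled = F.bilinear_sample(
            feats[int(lv)], np.zeros_like(grid_y, dtype=np.int64), grid_y, grid_x
        )  # (R_g, out, out, C)
        pieces.append(sampled.transpose(0, 3, 1, 2))
        owners.append(idx)
    stacked = pieces[0] if len(pieces) == 1 else nn.concatenate(pieces, axis=0)
    order = np.concatenate(owners)
    inv = np.empty(R, dtype=np.int64)
    inv[order] = np.arange(R)
    return stacked[inv]


class MaskRCNN(nn.Module):
    def __init__(self, config: ModelConfig):
        super().__init__()
        nn.seed(config.seed)
        self.config = config
        self.backbone = Backbone(config.backbone_widths, config.backbone_blocks)
        attach_attention(self.backbone, config.attention)
        self.pyramid = FeaturePyramid(self.backbone.stage_channels, config.pyramid)
        max_a = max(config.anchors.anchors_per_cell(k) for k in range(2, 7))
        self.rpn_head = RPNHead(config.pyramid.width, max_a)
        self.box_head = BoxHead(
            config.pyramid.width, config.roi_size, config.box_head_hidden, config.num_classes
        )
        self.mask_head = MaskHead(config.pyramid.width, config.num_classes)
        self._eval_assign = dataclasses.replace(
            config.assign,
            pre_nms_topk=config.eval_pre_nms_topk,
            post_nms_topk=config.eval_post_nms_topk,
        )

    # -- plumbing ----------------------------------------------------------
    def features(self, x: Tensor) -> dict[int, Tensor]:
        """Prediction levels keyed by level number (2..6)."""
        p = self.pyramid(self.backbone(x))
        return {int(k[1]): v for k, v in p.items()}

    def _level_geometry(self, feats: dict[int, Tensor]):
        dims = {k: tuple(v.shape[2:]) for k, v in feats.items()}
        strides = {k: 2**k for k in feats}
        return dims, strides

    def _rpn_outputs(self, feats: dict[int, Tensor]):
        obj, deltas = {}, {}
        for k, f in feats.items():
            a = self.config.anchors.anchors_per_cell(k)
            o, d = self.rpn_head(f, a)
            obj[k], deltas[k] = o.reshape(-1), d.reshape(-1, 4)
        return obj, deltas

    def _proposals(self, obj, deltas, anchors, image_size, assign: AssignmentConfig):
        scores = {k: 1.0 / (1.0 + np.exp(-obj[k].data.astype(np.float64))) for k in obj}
        raw = {k: deltas[k].data for k in deltas}
        return propose(scores, raw, anchors, image_size, assign)

    # -- training ----------------------------------------------------------
    def losses(self, image: np.ndarray, annotations: list[InstanceAnnotation],
               rng: np.random.Generator) -> dict[str, Tensor]:
        """Five-component loss for one image (finite for any input)."""
        cfg = self.config
        H, W = image.shape[:2]
        x = normalize_image(image)
        feats = self.features(x)
        dims, strides = self._level_geometry(feats)
        anchors = generate_anchors(dims, strides, cfg.anchors)
        obj, deltas = self._rpn_outputs(feats)

        gt_boxes = np.array([a.bbox for a in annotations], dtype=np.float64).reshape(-1, 4)
        gt_labels = np.array([a.category_id for a in annotations], dtype=np.int64)

        levels = sorted(anchors)
        anchors_cat = np.concatenate([anchors[k] for k in levels])
        obj_cat = nn.concatenate([obj[k] for k in levels], axis=0)
        deltas_cat = nn.concatenate([deltas[k] for k in levels], axis=0)

        labels = assign_fg_bg(anchors_cat, gt_boxes, cfg.assign)
        fg_idx = np.flatnonzero(labels == 1)
        bg_idx = np.flatnonzero(labels == 0)
        n_fg = min(len(fg_idx), cfg.rpn_batch_size // 2)
        n_bg = min(len(bg_idx), cfg.rpn_batch_size - n_fg)
        fg_s = rng.choice(fg_idx, n_fg, replace=False) if n_fg else np.empty(0, np.int64)
        bg_s = rng.choice(bg_idx, n_bg, replace=False) if n_bg else np.empty(0, np.int64)
        sampled = np.concatenate([fg_s, bg_s]).astype(np.int64)
        targets = np.concatenate([np.ones(n_fg), np.zeros(n_bg)])
        rpn_cls = F.bce_with_logits(obj_cat[sampled], targets)

        if n_fg:
            m = box_iou_matrix(anchors_cat[fg_s], gt_boxes)
            matched = gt_boxes[m.argmax(axis=1)]
            reg_t = encode_deltas(anchors_cat[fg_s], matched)
            rpn_reg = F.smooth_l1(deltas_cat[fg_s], reg_t, divisor=max(len(sampled), 1))
        else:
            rpn_reg = Tensor(np.float32(0.0))

        # -- second stage ---------------------------------------------------
        props = self._proposals(obj, deltas, anchors, (H, W), cfg.assign)
        prop_boxes = props.boxes
        if len(gt_boxes):
            prop_boxes = np.concatenate([prop_boxes, gt_boxes])  # GT-augmented sampling
        if len(gt_boxes) == 0 or len(prop_boxes) == 0:
            zero = Tensor(np.float32(0.0))
            return {"rpn_cls": rpn_cls, "rpn_reg": rpn_reg, "box_cls": zero,
                    "box_reg": zero, "mask": zero}

        m = box_iou_matrix(prop_boxes, gt_boxes)
        best_gt = m.argmax(axis=1)
        best_iou = m.max(axis=1)
        roi_labels = np.where(best_iou >= 0.5, gt_labels[best_gt], 0)
        fg_rois = np.flatnonzero(roi_labels > 0)
        bg_rois = np.flatnonzero(roi_labels == 0)
        n_fg = min(len(fg_rois), int(cfg.roi_batch_size * cfg.roi_fg_fraction))
        n_bg = min(len(bg_rois), cfg.roi_batch_size - n_fg)
        fg_sel = rng.choice(fg_rois, n_fg, replace=False) if n_fg else np.empty(0, np.int64)
        bg_sel = rng.choice(bg_rois, n_bg, replace=False) if n_bg else np.empty(0, np.int64)
        sel = np.concatenate([fg_sel, bg_sel]).astype(np.int64)
        sel_boxes = prop_boxes[sel]
        sel_labels = roi_labels[sel]

        roi_feats = roi_align(feats, strides, sel_boxes, cfg.roi_size)
        cls_logits, reg = self.box_head(roi_feats)
        box_cls = F.softmax_cross_entropy(cls_logits, sel_labels)
        if n_fg:
            reg_t = encode_deltas(sel_boxes[:n_fg], gt_boxes[best_gt[fg_sel]])
            box_reg = F.smooth_l1(
                reg[:n_fg], reg_t * _BOX_REG_WEIGHTS, beta=1.0, divisor=max(len(sel), 1)
            )
        else:
            box_reg = Tensor(np.float32(0.0))

        if n_fg:
            mask_feats = roi_align(feats, strides, sel_boxes[:n_fg], cfg.mask_roi_size)
            mask_logits = self.mask_head(mask_feats)  # (n_fg, K, 28, 28)
            rows = np.arange(n_fg)
            chan = sel_labels[:n_fg] - 1
            picked = mask_logits[rows, chan]
            mt = np.stack(
                [
                    _crop_mask(annotations[best_gt[fg_sel[i]]].mask, sel_boxes[i], 28)
                    for i in range(n_fg)
                ]
            )
            mask_loss = F.bce_with_logits(picked, mt)
        else:
            mask_loss = Tensor(np.float32(0.0))

        return {"rpn_cls": rpn_cls, "rpn_reg": rpn_reg, "box_cls": box_cls,
                "box_reg": box_reg, "mask": mask_loss}

    # -- inference ---------------------------------------------------------
    def predict(self, image: np.ndarray, confidence: float | None = None) -> DetectionResult:
        """Detect kernels in one RGB image (deterministic in eval mode)."""
        cfg = self.config
        conf = cfg.confidence if confidence is None else confidence
        H, W = image.shape[:2]
        x = normalize_image(image)
        feats = self.features(x)
        dims, strides = self._level_geometry(feats)
        anchors = generate_anchors(dims, strides, cfg.anchors)
        obj, deltas = self._rpn_outputs(feats)
        props = self._proposals(obj, deltas, anchors, (H, W), self._eval_assign)
        if len(props.boxes) == 0:
            return DetectionResult(
                np.empty((0, 4)), np.empty(0, np.int64), np.empty(0), np.empty((0, H, W), bool)
            )
        roi_feats = roi_align(feats, strides, props.boxes, cfg.roi_size)
        cls_logits, reg = self.box_head(roi_feats)
        probs = _softmax_np(cls_logits.data)
        refined = decode_deltas(props.boxes, reg.data.astype(np.float64) / _BOX_REG_WEIGHTS)
        refined = clip_boxes(refined, (H, W))

        keep_boxes, keep_scores, keep_labels = [], [], []
        for c in range(1, cfg.num_classes + 1):
            sc = probs[:, c]
            ok = sc >= conf
            if not ok.any():
                continue
            b, s = refined[ok], sc[ok]
            wh = np.minimum(b[:, 2] - b[:, 0], b[:, 3] - b[:, 1])
            good = wh >= 1.0
            b, s = b[good], s[good]
            if len(b) == 0:
                continue
            kept = nms(b, s, cfg.detection_nms_iou)
            keep_boxes.append(b[kept])
            keep_scores.append(s[kept])
            keep_labels.append(np.full(len(kept), c, dtype=np.int64))
        if not keep_boxes:
            return DetectionResult(
                np.empty((0, 4)), np.empty(0, np.int64), np.empty(0), np.empty((0, H, W), bool)
            )
        boxes = np.concatenate(keep_boxes)
        scores = np.concatenate(keep_scores)
        labels = np.concatenate(keep_labels)
        order = np.argsort(-scores, kind="stable")
        boxes, scores, labels = boxes[order], scores[order], labels[order]

        mask_feats = roi_align(feats, strides, boxes, cfg.mask_roi_size)
        mask_logits = self.mask_head(mask_feats).data
        masks = np.zeros((len(boxes), H, W), dtype=bool)
        for i, (b, l) in enumerate(zip(boxes, labels)):
            masks[i] = _paste_mask(mask_logits[i, l - 1], b, (H, W))
        return DetectionResult(boxes, labels, scores, masks)


def _softmax_np(z: np.ndarray) -> np.ndarray:
    z = z.astype(np.float64)
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _crop_mask(mask: np.ndarray, box: np.ndarray, out: int) -> np.ndarray:
    """Nearest-neighbour crop of a GT mask to a box, resized to out×out."""
    H, W = mask.shape
    x1, y1, x2, y2 = box
    cell = (np.arange(out) + 0.5) / out
    ys = np.clip((y1 + cell * (y2 - y1)).astype(np.int64), 0, H - 1)
    xs = np.clip((x1 + cell * (x2 - x1)).astype(np.int64), 0, W - 1)
    return mask[np.ix_(ys, xs)].astype(np.float64)


def _paste_mask(logits28: np.ndarray, box: np.ndarray, image_size: tuple[int, int],
                threshold: float = 0.5) -> np.ndarray:
    """Bilinearly resample 28×28 mask logits into the box, then threshold."""
    H, W = image_size
    x1, y1, x2, y2 = box
    out = np.zeros((H, W), dtype=bool)
    xi1, yi1 = int(math.floor(x1)), int(math.floor(y1))
    xi2, yi2 = int(math.ceil(x2)), int(math.ceil(y2))
    xi1, yi1 = max(xi1, 0), max(yi1, 0)
    xi2, yi2 = min(xi2, W), min(yi2, H)
    if xi2 <= xi1 or yi2 <= yi1:
        return out
    n = logits28.shape[0]
    ys = ((np.arange(yi1, yi2) + 0.5 - y1) / max(y2 - y1, 1e-6)) * n - 0.5
    xs = ((np.arange(xi1, xi2) + 0.5 - x1) / max(x2 - x1, 1e-6)) * n - 0.5
    prob = 1.0 / (1.0 + np.exp(-_bilinear_grid(logits28, ys, xs)))
    out[yi1:yi2, xi1:xi2] = prob >= threshold
    return out


def _bilinear_grid(img: np.ndarray, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    n, m = img.shape
    y0 = np.clip(np.floor(ys).astype(np.int64), 0, n - 1)
    x0 = np.clip(np.floor(xs).astype(np.int64), 0, m - 1)
    y1 = np.minimum(y0 + 1, n - 1)
    x1 = np.minimum(x0 + 1, m - 1)
    wy = np.clip(ys - y0, 0, 1)[:, None]
    wx = np.clip(xs - x0, 0, 1)[None, :]
    return (
        img[np.ix_(y0, x0)] * (1 - wy) * (1 - wx)
        + img[np.ix_(y0, x1)] * (1 - wy) * wx
        + img[np.ix_(y1, x0)] * wy * (1 - wx)
        + img[np.ix_(y1, x1)] * wy * wx
    )


# --------------------------------------------------------------------------
# public API
# --------------------------------------------------------------------------

def build_model(config: ModelConfig) -> MaskRCNN:
    """Build a detector; weights are reproducible from ``config.seed``."""
    return MaskRCNN(config)


def count_parameters(model: nn.Module) -> int:
    """Total number of trainable scalars."""
    return model.num_parameters()


def train_step(model: MaskRCNN, batch: list[tuple[np.ndarray, list[InstanceAnnotation]]],
               optimizer: nn.SGD, rng: np.random.Generator) -> dict[str, float]:
    """One SGD step on a batch of (image, annotations) pairs.

    Returns the scalar loss components (averaged over the batch) plus their
    sum under ``"total"``.
    """
    optimizer.zero_grad()
    comp_names = ("rpn_cls", "rpn_reg", "box_cls", "box_reg", "mask")
    total = None
    sums = dict.fromkeys(comp_names, 0.0)
    for image, anns in batch:
        losses = model.losses(image, anns, rng)
        for k in comp_names:
            sums[k] += losses[k].item()
        s = losses["rpn_cls"] + losses["rpn_reg"] + losses["box_cls"] + losses["box_reg"] + losses["mask"]
        total = s if total is None else total + s
    loss = total * (1.0 / len(batch))
    loss.backward()
    optimizer.step()
    out = {k: v / len(batch) for k, v in sums.items()}
    out["total"] = sum(out.values())
    return out


def fit(model: MaskRCNN, dataset: list[tuple[np.ndarray, list[InstanceAnnotation]]],
        iterations: int, lr: float | None = None, seed: int = 0,
        batch_size: int | None = None, log_every: int = 0,
        callback=None) -> list[dict[str, float]]:
    """Train for a fixed iteration budget over a (small, in-memory) dataset.

    Images are drawn in shuffled epochs; a linear warm-up ramps the learning
    rate over the configured warm-up span.  Returns the per-iteration loss
    history.
    """
    tc = model.config.train
    lr = tc.lr if lr is None else lr
    batch_size = tc.batch if batch_size is None else batch_size
    opt = nn.SGD(
        list(model.parameters()), lr=lr, momentum=tc.momentum,
        weight_decay=tc.weight_decay, clip_grad_norm=tc.clip_grad_norm,
    )
    warmup_iters = min(tc.warmup_iters, max(iterations // 3, 1))
    sched = nn.WarmupSchedule(opt, lr, warmup_iters, tc.warmup_factor)
    rng = np.random.default_rng(seed)
    history = []
    order: list[int] = []
    model.train()
    for it in range(iterations):
        batch = []
        for _ in range(batch_size):
            if not order:
                order = list(rng.permutation(len(dataset)))
            batch.append(dataset[order.pop()])
        stats = train_step(model, batch, opt, rng)
        sched.step()
        stats["iteration"] = it
        stats["lr"] = opt.lr
        history.append(stats)
        if log_every and (it + 1) % log_every == 0:
            print(f"iter {it + 1}/{iterations} total {stats['total']:.4f}")
        if callback is not None:
            callback(it, stats)
    model.eval()
    return history


def save_checkpoint(model: MaskRCNN, path) -> None:
    """Write weights + embedded config to an .npz checkpoint."""
    import json as _json

    from .config import _to_plain

    state = {f"param/{k}": v for k, v in model.state_dict().items()}
    state["config_json"] = np.frombuffer(
        _json.dumps(_to_plain(model.config)).encode(), dtype=np.uint8
    )
    np.savez(path, **state)


def load_checkpoint(path) -> MaskRCNN:
    """Rebuild a model from a checkpoint written by :func:`save_checkpoint`."""
    import json as _json

    from .config import config_from_dict

    with np.load(path) as z:
        cfg = config_from_dict(_json.loads(bytes(z["config_json"].tobytes()).decode()))
        model = MaskRCNN(cfg)
        model.load_state_dict(
            {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
        )
    model.eval()
    return model


def predict_dataset(model: MaskRCNN, images: list[np.ndarray],
                    confidence: float | None = None,
                    timed: bool = False) -> tuple[list[DetectionResult], float]:
    """Run inference over a list of images; returns results and seconds/image."""
    t0 = time.perf_counter()
    results = [model.predict(img, confidence) for img in images]
    dt = (time.perf_counter() - t0) / max(len(images), 1)
    return results, dt
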