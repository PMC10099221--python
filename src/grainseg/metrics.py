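"""Evaluation: greedy prediction-to-truth matching, precision/recall,
AP/mAP, AR, and per-class pixel IoU/mIoU.

recall = TP / (TP + FN), precision = TP / (TP + FP), IoU(E, F) = |E∩F| / |E∪F|
with E the predicted region and F the ground-truth region.  AP is the area
under the precision-recall curve (all-point interpolation: the precision
envelope integrated over recall); mAP and mIoU are unweighted means over
the classes present in the ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .rpn import box_iou_matrix
from .synthetic import CATEGORIES, InstanceAnnotation

__all__ = [
    "ConfusionCounts",
    "MatchSpec",
    "Detection",
    "MetricReport",
    "match",
    "precision",
    "recall",
    "mask_iou",
    "average_precision",
    "mean_ap",
    "evaluate_detections",
]


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0
    TN: int = 0  # unused in detection; kept for completeness

    def __post_init__(self):
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class MatchSpec:
    iou_threshold: float = 0.5
    iou_kind: str = "mask"  # or "box"

    def __post_init__(self):
        if not (0.0 < self.iou_threshold < 1.0):
            raise ValueError("iou_threshold must lie in (0, 1)")
        if self.iou_kind not in ("mask", "box"):
            raise ValueError("iou_kind must be 'mask' or 'box'")


@dataclass
class Detection:
    """One predicted instance."""

    category_id: int
    score: float
    box: tuple[float, float, float, float]
    mask: np.ndarray | None = None  # bool (H, W)


@dataclass
class MetricReport:
    per_class_ap: dict[str, float]
    map: float
    per_class_recall: dict[str, float]
    ar: float
    per_class_iou: dict[str, float]
    miou: float
    precision: float
    recall: float
    counts: ConfusionCounts
    parameters: int | None = None
    seconds_per_image: float | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_class_ap": self.per_class_ap,
            "mAP": self.map,
            "per_class_recall": self.per_class_recall,
            "AR": self.ar,
            "per_class_iou": self.per_class_iou,
            "mIoU": self.miou,
            "precision": self.precision,
            "recall": self.recall,
            "counts": {"TP": self.counts.TP, "FP": self.counts.FP, "FN": self.counts.FN},
            "parameters": self.parameters,
            "seconds_per_image": self.seconds_per_image,
            **self.extra,
        }

    def to_table(self) -> str:
        """Human-readable summary mirroring the usual validation tables."""
        lines = [
            f"{'class':<10} {'AP':>6} {'recall':>7} {'IoU':>6}",
        ]
        for name in self.per_class_ap:
            lines.append(
                f"{name:<10} {self.per_class_ap[name]:>6.3f} "
                f"{self.per_class_recall.get(name, float('nan')):>7.3f} "
                f"{self.per_class_iou.get(name, float('nan')):>6.3f}"
            )
        lines.append(
            f"{'mean':<10} {self.map:>6.3f} {self.ar:>7.3f} {self.miou:>6.3f}"
        )
        lines.append(f"precision {self.precision:.3f}  recall {self.recall:.3f}")
        if self.parameters is not None:
            lines.append(f"parameters {self.parameters}")
        if self.seconds_per_image is not None:
            lines.append(f"time/s {self.seconds_per_image:.3f}")
        return "\n".join(lines)


def precision(counts: ConfusionCounts) -> float:
    if counts.TP + counts.FP == 0:
        warnings.warn("precision undefined (TP+FP == 0); returning 0")
        return 0.0
    return counts.TP / (counts.TP + counts.FP)


def recall(counts: ConfusionCounts) -> float:
    if counts.TP + counts.FN == 0:
        warnings.warn("recall undefined (TP+FN == 0); returning 0")
        return 0.0
    return counts.TP / (counts.TP + counts.FN)


def mask_iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """|A∩B| / |A∪B| of two binary rasters of identical shape."""
    if mask_a.shape != mask_b.shape:
        raise ValueError(f"mask shapes differ: {mask_a.shape} vs {mask_b.shape}")
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        warnings.warn("IoU of two empty masks is defined as 0")
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def _pair_iou(pred: Detection, gt: InstanceAnnotation, kind: str) -> float:
    if kind == "mask":
        if pred.mask is None:
            raise ValueError("mask IoU requested but prediction has no mask")
        return mask_iou(pred.mask, gt.mask)
    m = box_iou_matrix(np.asarray(pred.box)[None], np.asarray(gt.bbox)[None])
    return float(m[0, 0])


def match(predictions: list[Detection], ground_truths: list[InstanceAnnotation],
          spec: MatchSpec = MatchSpec()) -> tuple[np.ndarray, np.ndarray, int]:
    """Greedy score-ordered matching of predictions onto ground truths.

    Returns ``(order, tp_flags, fn)``: ``order`` gives prediction indices in
    descending-score (greedy) order, ``tp_flags[i]`` says whether
    ``predictions[order[i]]`` matched an unused same-class ground truth at
    IoU >= threshold, and ``fn`` counts ground truths left unmatched.
    """
    order = np.argsort([-p.score for p in predictions], kind="stable")
    used = np.zeros(len(ground_truths), dtype=bool)
    tp = np.zeros(len(predictions), dtype=bool)
    for rank, pi in enumerate(order):
        p = predictions[pi]
        best_iou, best_gt = 0.0, -1
        for gi, gt in enumerate(ground_truths):
            if used[gi] or gt.category_id != p.category_id:
                continue
            v = _pair_iou(p, gt, spec.iou_kind)
            if v > best_iou:
                best_iou, best_gt = v, gi
        if best_gt >= 0 and best_iou >= spec.iou_threshold:
            used[best_gt] = True
            tp[rank] = True
    return order, tp, int(len(ground_truths) - used.sum())


def average_precision(scores: np.ndarray, tp_flags: np.ndarray, n_gt: int,
                      interpolation: str = "all_point") -> float:
    """Area under the precision-recall curve swept over the score threshold.

    ``all_point`` integrates the precision envelope over recall;
    ``coco101`` samples the envelope at 101 evenly spaced recall points.
    """
    if n_gt < 1:
        raise ValueError("average_precision requires n_gt >= 1")
    if int(np.sum(tp_flags)) > n_gt:
        raise ValueError("more true positives than ground truths")
    if len(scores) == 0:
        return 0.0
    order = np.argsort(-np.asarray(scores, dtype=np.float64), kind="stable")
    tp = np.asarray(tp_flags, dtype=np.float64)[order]
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(1.0 - tp)
    rec = cum_tp / n_gt
    prec = cum_tp / (cum_tp + cum_fp)
    # precision envelope (running max from the right)
    env = np.maximum.accumulate(prec[::-1])[::-1]
    if interpolation == "coco101":
        pts = np.linspace(0, 1, 101)
        idx = np.searchsorted(rec, pts, side="left")
        vals = np.where(idx < len(env), env[np.minimum(idx, len(env) - 1)], 0.0)
        return float(vals.mean())
    r_prev = np.concatenate([[0.0], rec[:-1]])
    return float(((rec - r_prev) * env).sum())


def mean_ap(per_class_aps: dict[str, float] | list[float]) -> float:
    vals = list(per_class_aps.values()) if isinstance(per_class_aps, dict) else list(per_class_aps)
    if not vals:
        warnings.warn("mean AP of zero classes is defined as 0")
        return 0.0
    return float(np.mean(vals))


def evaluate_detections(
    predictions_per_image: list[list[Detection]],
    ground_truths_per_image: list[list[InstanceAnnotation]],
    spec: MatchSpec = MatchSpec(),
    interpolation: str = "all_point",
) -> MetricReport:
    """Dataset-level evaluation.

    Per class: detections are pooled over images, matched greedily per
    image, and summarized as AP (threshold sweep) and recall at the given
    operating point.  Per-class pixel IoU compares the union of predicted
    masks with the union of ground-truth masks of that class.  Classes with
    no ground truth are excluded from the means (with a warning).
    """
    if len(predictions_per_image) != len(ground_truths_per_image):
        raise ValueError("prediction and ground-truth lists differ in length")
    names = {c.id: c.name for c in CATEGORIES}
    per_class: dict[int, dict] = {
        cid: {"scores": [], "tp": [], "n_gt": 0, "inter": 0, "union": 0, "fn": 0}
        for cid in names
    }
    for preds, gts in zip(predictions_per_image, ground_truths_per_image):
        for cid in names:
            c_preds = [p for p in preds if p.category_id == cid]
            c_gts = [g for g in gts if g.category_id == cid]
            order, tp, fn = match(c_preds, c_gts, spec)
            acc = per_class[cid]
            acc["scores"].extend(c_preds[i].score for i in order)
            acc["tp"].extend(tp.tolist())
            acc["n_gt"] += len(c_gts)
            acc["fn"] += fn
            if spec.iou_kind == "mask" or c_gts or c_preds:
                gmask = None
                pmask = None
                for g in c_gts:
                    gmask = g.mask if gmask is None else (gmask | g.mask)
                for p in c_preds:
                    if p.mask is not None:
                        pmask = p.mask if pmask is None else (pmask | p.mask)
                if gmask is not None or pmask is not None:
                    shape = gmask.shape if gmask is not None else pmask.shape
                    gmask = gmask if gmask is not None else np.zeros(shape, bool)
                    pmask = pmask if pmask is not None else np.zeros(shape, bool)
                    acc["inter"] += int((gmask & pmask).sum())
                    acc["union"] += int((gmask | pmask).sum())

    per_ap: dict[str, float] = {}
    per_rec: dict[str, float] = {}
    per_iou: dict[str, float] = {}
    tot = ConfusionCounts()
    for cid, acc in per_class.items():
        name = names[cid]
        n_tp = int(sum(acc["tp"]))
        n_fp = len(acc["tp"]) - n_tp
        tot.TP += n_tp
        tot.FP += n_fp
        tot.FN += acc["fn"]
        if acc["n_gt"] == 0:
            if acc["scores"]:
                warnings.warn(f"class {name!r} has predictions but no ground truth; excluded")
            continue
        per_ap[name] = average_precision(
            np.asarray(acc["scores"]), np.asarray(acc["tp"]), acc["n_gt"], interpolation
        )
        per_rec[name] = n_tp / acc["n_gt"]
        per_iou[name] = acc["inter"] / acc["union"] if acc["union"] else 0.0

    return MetricReport(
        per_class_ap=per_ap,
        map=mean_ap(per_ap) if per_ap else 0.0,
        per_class_recall=per_rec,
        ar=float(np.mean(list(per_rec.values()))) if per_rec else 0.0,
        per_class_iou=per_iou,
        miou=float(np.mean(list(per_iou.values()))) if per_iou else 0.0,
        precision=precision(tot) if (tot.TP + tot.FP) else 0.0,
        recall=recall(tot) if (tot.TP + tot.FN) else 0.0,
        counts=tot,
    )
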