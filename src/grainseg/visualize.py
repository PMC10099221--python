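"""Prediction overlays with the fixed per-class color map."""

from __future__ import annotations

import numpy as np

__all__ = ["CLASS_COLORS", "overlay"]

# perfect orange, moldy yellow, injured green, spotted blue, sprouted purple, broken red
CLASS_COLORS = {
    1: (255, 140, 0),
    2: (255, 215, 0),
    3: (0, 200, 80),
    4: (30, 100, 255),
    5: (160, 60, 220),
    6: (230, 40, 40),
}


def overlay(image: np.ndarray, result, alpha: float = 0.45,
            draw_boxes: bool = True) -> np.ndarray:
    """Tint instance masks by class color and outline boxes.

    ``result`` may be a DetectionResult or a list of InstanceAnnotation.
    """
    out = image.astype(np.float64).copy()
    if isinstance(result, list):
        items = [(a.category_id, a.bbox, a.mask) for a in result]
    else:
        items = list(zip(result.labels, result.boxes, result.masks))
    for cid, box, mask in items:
        color = np.array(CLASS_COLORS[int(cid)], dtype=np.float64)
        out[mask] = (1 - alpha) * out[mask] + alpha * color
        if draw_boxes:
            H, W = out.shape[:2]
            x1, y1, x2, y2 = (int(round(v)) for v in box)
            x1, y1 = max(x1, 0), max(y1, 0)
            x2, y2 = min(x2, W - 1), min(y2, H - 1)
            out[y1, x1:x2] = color
            out[y2, x1:x2] = color
            out[y1:y2, x1] = color
            out[y1:y2, x2] = color
    return np.clip(out, 0, 255).astype(np.uint8)
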