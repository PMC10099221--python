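"""Region-proposal geometry: anchors, IoU screening, and low-threshold NMS.

Six anchor scales {8..256} at ratios {0.5, 1, 2} are spread over the
pyramid levels.  Candidates overlapping a ground truth above 0.7 are
foreground, below 0.3 background, and the band in between is discarded.
Proposal NMS runs at 0.5 so two adherent kernels are not merged into one.
"""

import numpy as np

from grainseg.rpn import (
    AnchorConfig,
    AssignmentConfig,
    anchor_shape,
    assign_fg_bg,
    generate_anchors,
    iou,
    nms,
)

cfg = AnchorConfig()
print("anchor (width, height) for scale 8:")
for r in cfg.ratios:
    w, h = anchor_shape(8, r)
    print(f"  ratio {r}: ({w:.3f}, {h:.3f})  area {w * h:.1f}")

dims = {k: (256 // 2**k, 256 // 2**k) for k in range(2, 7)}
anchors = generate_anchors(dims, {k: 2**k for k in dims}, cfg)
print("\nanchors per level on a 256x256 input:")
for k in sorted(anchors):
    print(f"  level {k} (stride {2**k:>2}): {len(anchors[k]):>6}")

print("\nIoU((0,0,10,10),(5,0,15,10)) =", round(iou((0, 0, 10, 10), (5, 0, 15, 10)), 4))

gt = np.array([[10, 10, 40, 40]], float)
cand = np.array([[11, 11, 41, 41], [10, 10, 40, 55], [60, 60, 90, 90]], float)
labels = assign_fg_bg(cand, gt, AssignmentConfig(), rescue=False)
print("fg/bg labels (1=fg, 0=bg, -1=discard):", labels.tolist())

boxes = np.array([(0, 0, 10, 10), (1, 1, 11, 11), (20, 20, 30, 30)], float)
kept = nms(boxes, np.array([0.9, 0.8, 0.7]), nms_iou=0.5)
print("NMS keeps boxes:", kept.tolist())
# Box 1 overlaps box 0 at IoU ~0.68 > 0.5 and is suppressed; box 2 survives.
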