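"""Evaluation closed forms: precision, recall, AP, and the per-class mean.

recall = TP/(TP+FN), precision = TP/(TP+FP), AP is the area under the
precision-recall curve, and mAP averages APs over classes.
"""

import numpy as np

from grainseg.metrics import (
    ConfusionCounts,
    average_precision,
    mean_ap,
    precision,
    recall,
)

print("precision(TP=86, FP=14) =", precision(ConfusionCounts(TP=86, FP=14)))
print("recall(TP=91, FN=9)     =", recall(ConfusionCounts(TP=91, FN=9)))

# two detections (one TP at score .9, one FP at .8) against two ground truths:
ap = average_precision(np.array([0.9, 0.8]), np.array([True, False]), n_gt=2)
print("AP of the two-detection example =", ap)

per_class = {"perfect": 0.60, "moldy": 0.99, "injured": 0.82,
             "spotted": 0.89, "sprouted": 0.89, "broken": 0.98}
m = mean_ap(per_class)
print(f"mean of six per-class APs = {m:.4f} (rounds to {round(m, 2)})")
# The unweighted class mean is the headline mAP; a strong class (moldy)
# cannot mask a weak one (perfect) because every class counts equally.
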