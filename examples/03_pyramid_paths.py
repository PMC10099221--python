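"""Feature pyramids: top-down baseline vs the bottom-up fusion path.

The bottom-up path takes the P-levels and re-fuses them fine-to-coarse:
N2 = P2, then N(k+1) = conv3x3(pool(Nk) + P(k+1)).  Localization-rich
low-level signal reaches the coarsest prediction level in three fusion
steps instead of traversing the whole backbone.
"""

import numpy as np

from grainseg import nn
from grainseg.nn.tensor import Tensor
from grainseg.pyramid import FeaturePyramid, PyramidConfig

CH = {"C2": 16, "C3": 24, "C4": 32, "C5": 48}
rng = np.random.default_rng(0)
feats = {
    lv: Tensor(rng.normal(size=(1, c, 64 // 2**i, 64 // 2**i)).astype(np.float32))
    for i, (lv, c) in enumerate(CH.items())
}

for kind in ("fpn", "bottom_up", "rfpn"):
    nn.seed(0)
    fp = FeaturePyramid(CH, PyramidConfig(kind, width=16))
    out = fp(feats)
    shapes = {k: tuple(v.shape[2:]) for k, v in out.items()}
    print(f"{kind:<10} params {fp.num_parameters():>6}  levels {shapes}")

# N2 is P2 bit-exactly (no extra convolution on the finest level):
nn.seed(0)
fp = FeaturePyramid(CH, PyramidConfig("bottom_up", width=16))
p = fp.top_down(feats)
n = fp.bottom_up({k: p[k] for k in ("P2", "P3", "P4", "P5")})
print("\nN2 is P2:", n["N2"] is p["P2"])
# All prediction levels share one channel width; spatial sizes halve per level.
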