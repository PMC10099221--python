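"""Channel attention: adaptive ECA kernel sizes and parameter budgets.

ECA gates channels with a single shared 1-D convolution over the pooled
channel descriptor; its kernel size grows logarithmically with the channel
count.  SE uses a bottleneck MLP and CBAM adds a spatial gate, so the
parameter budgets order ECA < SE < CBAM.
"""

import numpy as np

from grainseg import nn
from grainseg.attention import CBAM, ECA, SE, eca_kernel_size
from grainseg.nn.tensor import Tensor

for c in (8, 64, 256, 512):
    print(f"ECA kernel size for {c:>3} channels: {eca_kernel_size(c)}")

nn.seed(0)
channels = 64
blocks = {"eca": ECA(channels), "se": SE(channels), "cbam": CBAM(channels)}
x = Tensor(np.random.default_rng(0).normal(size=(1, channels, 8, 8)).astype(np.float32))
print(f"\n{'block':<6} {'params':>7}  shape-preserving  attenuating-gate")
for name, block in blocks.items():
    out = block(x)
    ratio = np.abs(out.data) / np.maximum(np.abs(x.data), 1e-9)
    print(f"{name:<6} {block.num_parameters():>7}  "
          f"{out.shape == x.shape!s:<17} {bool((ratio < 1).all())}")
# The gate lies strictly in (0, 1): attention can only re-weight channels,
# never amplify them, and ECA achieves this with by far the fewest parameters.
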