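"""Channel-attention blocks for the backbone: ECA (primary), SE, CBAM.

All three re-weight feature channels with gates in (0, 1) computed from
global pooled descriptors; CBAM adds a spatial gate after the channel gate.
ECA replaces SE's fully connected bottleneck with a single shared 1-D
convolution across the channel descriptor whose kernel size adapts to the
channel count, which is why it adds the fewest parameters of the three.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor

__all__ = [
    "AttentionConfig",
    "eca_kernel_size",
    "ECA",
    "SE",
    "CBAM",
    "make_attention",
    "attach_attention",
]

ATTENTION_KINDS = ("eca", "se", "cbam", "none")


@dataclass(frozen=True)
class AttentionConfig:
    kind: str = "eca"
    eca_gamma: int = 2
    eca_b: int = 1
    se_reduction: int = 16
    cbam_spatial_kernel: int = 7

    def __post_init__(self):
        if self.kind not in ATTENTION_KINDS:
            raise ValueError(f"unknown attention kind {self.kind!r}; expected {ATTENTION_KINDS}")


def eca_kernel_size(channels: int, gamma: int = 2, b: int = 1) -> int:
    """Adaptive ECA kernel size: nearest odd integer to |log2(C)/γ + b/γ|, ≥ 1.

    The kernel grows logarithmically with the channel count so that wider
    layers aggregate a wider cross-channel neighbourhood.
    """
    if channels < 1:
        raise ValueError("channels must be >= 1")
    t = abs(math.log2(channels) / gamma + b / gamma)
    k = int(round(t))
    if k % 2 == 0:
        # round to the *nearest* odd integer
        k = k + 1 if t >= k else k - 1
    return max(k, 1)


def _check_finite(x: Tensor) -> None:
    if not np.isfinite(x.data).all():
        raise ValueError("attention input contains non-finite values")


class ECA(nn.Module):
    """Efficient channel attention: GAP -> shared 1-D conv over channels -> σ."""

    def __init__(self, channels: int, config: AttentionConfig = AttentionConfig()):
        super().__init__()
        self.k = eca_kernel_size(channels, config.eca_gamma, config.eca_b)
        self.conv = nn.Parameter(np.zeros(self.k))  # bias-free by construction
        self.conv.data[self.k // 2] = 1.0  # identity-neighbourhood init

    def forward(self, x: Tensor) -> Tensor:
        _check_finite(x)
        N, C, H, W = x.shape
        pooled = F.global_avg_pool(x)  # (N, C)
        gate = F.conv1d_channels(pooled, self.conv, self.k).sigmoid()
        return x * gate.reshape(N, C, 1, 1)


class SE(nn.Module):
    """Squeeze-and-excitation: GAP -> bottleneck MLP (C -> C/r -> C) -> σ."""

    def __init__(self, channels: int, config: AttentionConfig = AttentionConfig()):
        super().__init__()
        hidden = max(channels // config.se_reduction, 1)
        self.fc1 = nn.Linear(channels, hidden)
        self.fc2 = nn.Linear(hidden, channels)

    def forward(self, x: Tensor) -> Tensor:
        _check_finite(x)
        N, C, H, W = x.shape
        pooled = F.global_avg_pool(x)
        gate = self.fc2(self.fc1(pooled).relu()).sigmoid()
        return x * gate.reshape(N, C, 1, 1)


class CBAM(nn.Module):
    """Convolutional block attention: channel gate, then a spatial gate built
    from per-pixel channel mean/max maps passed through a k×k conv."""

    def __init__(self, channels: int, config: AttentionConfig = AttentionConfig()):
        super().__init__()
        hidden = max(channels // config.se_reduction, 1)
        self.fc1 = nn.Linear(channels, hidden)
        self.fc2 = nn.Linear(hidden, channels)
        k = config.cbam_spatial_kernel
        self.spatial = nn.Conv2d(2, 1, k, padding=k // 2)

    def forward(self, x: Tensor) -> Tensor:
        _check_finite(x)
        N, C, H, W = x.shape
        # channel gate from both average- and max-pooled descriptors
        avg = F.global_avg_pool(x)
        mx = x.reshape(N, C, H * W).max(axis=2)
        gate_c = (
            self.fc2(self.fc1(avg).relu()) + self.fc2(self.fc1(mx).relu())
        ).sigmoid()
        x = x * gate_c.reshape(N, C, 1, 1)
        # spatial gate
        s_avg = x.mean(axis=1, keepdims=True)
        s_max = x.max(axis=1, keepdims=True)
        gate_s = self.spatial(nn.concatenate([s_avg, s_max], axis=1)).sigmoid()
        return x * gate_s


_BLOCKS = {"eca": ECA, "se": SE, "cbam": CBAM}


def make_attention(kind: str, channels: int, config: AttentionConfig | None = None) -> nn.Module:
    if kind == "none":
        return nn.Identity()
    if kind not in _BLOCKS:
        raise ValueError(f"unknown attention kind {kind!r}; expected {ATTENTION_KINDS}")
    cfg = config or AttentionConfig(kind=kind)
    return _BLOCKS[kind](channels, cfg)


def attach_attention(backbone, config: AttentionConfig):
    """Wrap each backbone stage output (C2..C5) in an attention block.

    ``backbone`` must expose ``stage_channels`` (a level->width map); with
    ``kind='none'`` the backbone is returned unchanged.
    """
    if config.kind == "none":
        return backbone
    blocks = {
        level: make_attention(config.kind, ch, config)
        for level, ch in backbone.stage_channels.items()
    }
    backbone.attention = nn.ModuleDict(blocks)
    return backbone
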