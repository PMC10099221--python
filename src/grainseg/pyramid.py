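"""Feature pyramids: top-down FPN, bottom-up fusion path, recursive FPN.

The top-down pyramid (P-levels) gives every scale semantic depth but leaves
shallow, localization-rich features a long path to the prediction head.
The bottom-up fusion path re-aggregates the P-levels from fine to coarse
(N-levels): N2 = P2 and each coarser level is a 3×3 convolution of the
downsampled previous N-level added to the matching P-level, so low-level
signal reaches the top prediction level in just three fusion steps.  When
the bottom-up path is used, the usual 3×3 smoothing of the P-levels is
removed (the bottom-up 3×3 convolutions take its place).  The recursive
variant instead projects the first-pass P-levels back onto the backbone
levels and runs the top-down route a second time.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor

__all__ = [
    "PyramidConfig",
    "TopDownFPN",
    "BottomUpPath",
    "RecursiveFPN",
    "FeaturePyramid",
    "build_pyramid",
    "PYRAMID_STRIDES",
]

PYRAMID_KINDS = ("fpn", "bottom_up", "rfpn")
PYRAMID_STRIDES = {"P2": 4, "P3": 8, "P4": 16, "P5": 32, "P6": 64}
C_LEVELS = ("C2", "C3", "C4", "C5")
P_LEVELS = ("P2", "P3", "P4", "P5")


@dataclass(frozen=True)
class PyramidConfig:
    kind: str = "bottom_up"
    width: int = 256
    downsample: str = "maxpool2"  # or "strided_conv"

    def __post_init__(self):
        if self.kind not in PYRAMID_KINDS:
            raise ValueError(f"unknown pyramid kind {self.kind!r}; expected {PYRAMID_KINDS}")
        if self.width <= 0:
            raise ValueError("pyramid width must be positive")
        if self.downsample not in ("maxpool2", "strided_conv"):
            raise ValueError(f"unknown downsample {self.downsample!r}")


def _check_c_levels(feats: dict[str, Tensor]) -> None:
    for lv in C_LEVELS:
        if lv not in feats:
            raise ValueError(f"missing backbone level {lv}")
    prev = None
    for lv in C_LEVELS:
        h, w = feats[lv].shape[2:]
        if prev is not None:
            ph, pw = prev
            if (ph + 1) // 2 != h or (pw + 1) // 2 != w:
                raise ValueError(
                    f"level {lv} spatial dims {(h, w)} are not half of the previous {(ph, pw)}"
                )
        prev = (h, w)


class TopDownFPN(nn.Module):
    """Lateral 1×1 projections + nearest-upsample-and-add top-down pathway.

    ``smooth=True`` applies the classic 3×3 output convolution per P-level;
    the bottom-up variant constructs this module with ``smooth=False``.
    P6 is a stride-2 subsampling of P5, used by the proposal stage only.
    """

    def __init__(self, in_channels: dict[str, int], width: int, smooth: bool = True):
        super().__init__()
        self.width = width
        self.smooth = smooth
        self.lateral = nn.ModuleDict(
            {lv: nn.Conv2d(in_channels[lv], width, 1) for lv in C_LEVELS}
        )
        if smooth:
            self.output = nn.ModuleDict(
                {f"P{lv[1]}": nn.Conv2d(width, width, 3, padding=1) for lv in C_LEVELS}
            )

    def forward(self, feats: dict[str, Tensor]) -> dict[str, Tensor]:
        _check_c_levels(feats)
        laterals = {f"P{lv[1]}": self.lateral[lv](feats[lv]) for lv in C_LEVELS}
        merged = {"P5": laterals["P5"]}
        for lv in ("P4", "P3", "P2"):
            upper = merged[f"P{int(lv[1]) + 1}"]
            merged[lv] = laterals[lv] + F.upsample_nearest2(upper)
        if self.smooth:
            merged = {lv: self.output[lv](merged[lv]) for lv in P_LEVELS}
        merged["P6"] = F.maxpool2d(merged["P5"], kernel=1, stride=2)
        return merged


class BottomUpPath(nn.Module):
    """Fine-to-coarse fusion over P-levels: N2 = P2,
    N_{k+1} = conv3×3(downsample(N_k) + P_{k+1})."""

    def __init__(self, width: int, downsample: str = "maxpool2"):
        super().__init__()
        self.width = width
        self.downsample_kind = downsample
        self.fuse = nn.ModuleDict(
            {lv: nn.Conv2d(width, width, 3, padding=1) for lv in ("N3", "N4", "N5")}
        )
        if downsample == "strided_conv":
            self.down = nn.ModuleDict(
                {lv: nn.Conv2d(width, width, 3, stride=2, padding=1) for lv in ("N3", "N4", "N5")}
            )

    def _down(self, x: Tensor, lv: str) -> Tensor:
        if self.downsample_kind == "maxpool2":
            return F.maxpool2d(x, kernel=2, stride=2)
        return self.down[lv](x)

    def forward(self, p_feats: dict[str, Tensor]) -> dict[str, Tensor]:
        for lv in P_LEVELS:
            if p_feats[lv].shape[1] != self.width:
                raise ValueError(
                    f"{lv} width {p_feats[lv].shape[1]} does not match pyramid width {self.width}"
                )
        n = {"N2": p_feats["P2"]}
        for k in (3, 4, 5):
            fused = self._down(n[f"N{k - 1}"], f"N{k}") + p_feats[f"P{k}"]
            n[f"N{k}"] = self.fuse[f"N{k}"](fused)
        n["N6"] = F.maxpool2d(n["N5"], kernel=1, stride=2)
        return n


class RecursiveFPN(nn.Module):
    """Second top-down pass: project P-levels back to backbone widths, add to
    the C-levels, and rerun the FPN route with its 3×3 output convolution.
    No spatial-pyramid (ASPP) block is used."""

    def __init__(self, in_channels: dict[str, int], width: int):
        super().__init__()
        self.first = TopDownFPN(in_channels, width, smooth=False)
        self.back = nn.ModuleDict(
            {lv: nn.Conv2d(width, in_channels[lv], 1) for lv in C_LEVELS}
        )
        self.second = TopDownFPN(in_channels, width, smooth=True)

    def forward(self, feats: dict[str, Tensor]) -> dict[str, Tensor]:
        p = self.first(feats)
        mixed = {lv: feats[lv] + self.back[lv](p[f"P{lv[1]}"]) for lv in C_LEVELS}
        return self.second(mixed)


class FeaturePyramid(nn.Module):
    """Dispatcher producing the prediction levels for a configured kind.

    Output keys are the prediction levels actually fed to the heads:
    N2..N6 for ``bottom_up``, P2..P6 otherwise; strides 4/8/16/32/64.
    """

    def __init__(self, in_channels: dict[str, int], config: PyramidConfig):
        super().__init__()
        self.config = config
        if config.kind == "fpn":
            self.net = TopDownFPN(in_channels, config.width, smooth=True)
        elif config.kind == "rfpn":
            self.net = RecursiveFPN(in_channels, config.width)
        else:
            self.top_down = TopDownFPN(in_channels, config.width, smooth=False)
            self.bottom_up = BottomUpPath(config.width, config.downsample)

    @property
    def level_names(self) -> list[str]:
        pre = "N" if self.config.kind == "bottom_up" else "P"
        return [f"{pre}{k}" for k in range(2, 7)]

    def forward(self, feats: dict[str, Tensor]) -> dict[str, Tensor]:
        if self.config.kind == "bottom_up":
            p = self.top_down(feats)
            return self.bottom_up({lv: p[lv] for lv in P_LEVELS})
        return self.net(feats)


def build_pyramid(in_channels: dict[str, int], config: PyramidConfig) -> FeaturePyramid:
    return FeaturePyramid(in_channels, config)
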