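"""Model/run configuration: the four model variants and their YAML form.

A *variant* fixes the (attention, pyramid) pair:

====================  =========  ===========
variant               attention  pyramid
====================  =========  ===========
baseline              none       fpn
am                    eca        fpn
fpn                   none       bottom_up
am_fpn (default)      eca        bottom_up
====================  =========  ===========

The ablation grid additionally combines {se, eca, cbam} × {rfpn, bottom_up}
via ``variant="custom"`` with explicit kinds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .attention import AttentionConfig
from .pyramid import PyramidConfig
from .rpn import AnchorConfig, AssignmentConfig

__all__ = ["TrainConfig", "ModelConfig", "VARIANTS", "ABLATION_GRID", "load_config", "save_config"]

VARIANTS = {
    "baseline": ("none", "fpn"),
    "am": ("eca", "fpn"),
    "fpn": ("none", "bottom_up"),
    "am_fpn": ("eca", "bottom_up"),
}

# the six attention × pyramid fusion combinations studied on top of the four variants
ABLATION_GRID = [
    ("se", "rfpn"),
    ("se", "bottom_up"),
    ("cbam", "rfpn"),
    ("cbam", "bottom_up"),
    ("eca", "rfpn"),
    ("eca", "bottom_up"),
]


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 0.00125
    batch: int = 4
    epochs: int = 50
    warmup_iters: int = 500
    warmup_factor: float = 0.1
    momentum: float = 0.9
    weight_decay: float = 1e-4
    clip_grad_norm: float = 10.0


@dataclass(frozen=True)
class ModelConfig:
    variant: str = "am_fpn"
    num_classes: int = 6  # foreground classes; background is implicit
    input_size: tuple[int, int] = (512, 512)
    backbone_widths: tuple[int, ...] = (32, 64, 128, 256)
    backbone_blocks: tuple[int, ...] = (2, 2, 2, 2)
    pyramid_width: int = 64
    box_head_hidden: int = 256
    roi_size: int = 7
    mask_roi_size: int = 14
    roi_batch_size: int = 64
    roi_fg_fraction: float = 0.25
    rpn_batch_size: int = 256
    confidence: float = 0.3  # detection score threshold
    detection_nms_iou: float = 0.5
    attention: AttentionConfig = field(default_factory=lambda: AttentionConfig("eca"))
    pyramid: PyramidConfig = field(default_factory=lambda: PyramidConfig("bottom_up"))
    anchors: AnchorConfig = field(default_factory=AnchorConfig)
    assign: AssignmentConfig = field(default_factory=AssignmentConfig)
    eval_pre_nms_topk: int = 1000
    eval_post_nms_topk: int = 500
    train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0

    def __post_init__(self):
        if self.variant != "custom":
            if self.variant not in VARIANTS:
                raise ValueError(
                    f"unknown variant {self.variant!r}; expected {list(VARIANTS)} or 'custom'"
                )
            att, pyr = VARIANTS[self.variant]
            if self.attention.kind != att or self.pyramid.kind != pyr:
                raise ValueError(
                    f"variant {self.variant!r} requires attention={att!r}, pyramid={pyr!r}; "
                    f"got attention={self.attention.kind!r}, pyramid={self.pyramid.kind!r}"
                )

    @staticmethod
    def from_variant(variant: str, tiny: bool = False, **overrides) -> "ModelConfig":
        """Construct a config for a named variant (or a custom kind pair).

        ``tiny=True`` selects the desk-scale preset: a one-block-per-stage
        backbone at widths (16, 24, 32, 48), pyramid width 16, 256×256 input.
        """
        if variant in VARIANTS:
            att, pyr = VARIANTS[variant]
        elif isinstance(variant, tuple):
            att, pyr = variant
            variant = "custom"
        else:
            raise ValueError(f"unknown variant {variant!r}")
        kw = dict(
            variant=variant,
            attention=AttentionConfig(att),
            pyramid=PyramidConfig(pyr, width=overrides.pop("pyramid_width", 16 if tiny else 64)),
        )
        if tiny:
            kw.update(
                input_size=(256, 256),
                backbone_widths=(16, 24, 32, 48),
                backbone_blocks=(1, 1, 1, 1),
                box_head_hidden=128,
                roi_batch_size=48,
                roi_fg_fraction=0.5,  # data-poor tiny runs benefit from more positives
                eval_pre_nms_topk=600,
                eval_post_nms_topk=150,
                assign=AssignmentConfig(pre_nms_topk=600, post_nms_topk=300),
            )
        kw.update(overrides)
        return ModelConfig(**kw)

    @staticmethod
    def custom(attention_kind: str, pyramid_kind: str, tiny: bool = False, **overrides) -> "ModelConfig":
        return ModelConfig.from_variant((attention_kind, pyramid_kind), tiny=tiny, **overrides)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def save_config(config: ModelConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=True))


def load_config(path: str | Path) -> ModelConfig:
    doc = yaml.safe_load(Path(path).read_text())
    return config_from_dict(doc)


def config_from_dict(doc: dict) -> ModelConfig:
    doc = dict(doc)
    if "attention" in doc:
        doc["attention"] = AttentionConfig(**doc["attention"])
    if "pyramid" in doc:
        doc["pyramid"] = PyramidConfig(**doc["pyramid"])
    if "anchors" in doc:
        a = dict(doc["anchors"])
        if "scales" in a:
            a["scales"] = tuple(a["scales"])
        if "ratios" in a:
            a["ratios"] = tuple(a["ratios"])
        if "level_assignment" in a:
            a["level_assignment"] = {int(k): tuple(v) for k, v in a["level_assignment"].items()}
        doc["anchors"] = AnchorConfig(**a)
    if "assign" in doc:
        doc["assign"] = AssignmentConfig(**doc["assign"])
    if "train" in doc:
        doc["train"] = TrainConfig(**doc["train"])
    for key in ("input_size", "backbone_widths", "backbone_blocks"):
        if key in doc:
            doc[key] = tuple(doc[key])
    return ModelConfig(**doc)
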