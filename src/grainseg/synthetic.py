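"""Synthetic scenes of densely packed wheat kernels with instance ground truth.

Real images of pooled grain show oval, yellow-white kernels lying against
each other ("adhesion"), with damaged classes distinguished by surface
appearance: gray mold patches, dark embryo-end disease spots, insect-bored
holes, a protruding sprout, or a broken/flattened outline.  This module
renders a controllable emulation of such scenes: each kernel is a rotated
ellipse (possibly deformed per class) with a class-specific texture,
occlusion is resolved by a z-order, and the ground truth records the
*visible* region of every kernel only — hidden parts are not annotated,
matching the labeling convention of grain datasets.

The module also implements the five augmentations used for such data
(brightness reduction, Gaussian noise, random salt points, translation,
horizontal flip) and a stratified 8:1:1 train/val/test split over the
composition strata (six single-class groups plus mixtures).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CATEGORY_NAMES",
    "CATEGORIES",
    "KernelCategory",
    "KernelInstance",
    "SceneSpec",
    "InstanceAnnotation",
    "DatasetRecord",
    "DatasetManifest",
    "category_by_name",
    "category_by_id",
    "sample_scene",
    "render_scene",
    "augment",
    "AUGMENT_METHODS",
    "AugmentParams",
    "build_dataset",
    "render_record",
    "split_counts",
]

CATEGORY_NAMES = ("perfect", "moldy", "injured", "spotted", "sprouted", "broken")

AUGMENT_METHODS = ("brightness", "noise", "points", "translate", "flip")

# kernel body colors (RGB), loosely "yellow-white skin"
_BASE_COLOR = np.array([205.0, 172.0, 115.0])
_BACKGROUND = np.array([58.0, 70.0, 88.0])  # dark tray


@dataclass(frozen=True)
class KernelCategory:
    id: int  # 1..6
    name: str

    @property
    def appearance(self) -> dict:
        """Class-level appearance recipe (texture motif + deformation flags)."""
        return _APPEARANCE[self.name]


_APPEARANCE = {
    "perfect": {"motif": "plain", "deform": None},
    "moldy": {"motif": "gray_patches", "deform": None},
    "injured": {"motif": "dark_holes", "deform": None},
    "spotted": {"motif": "embryo_blotch", "deform": None},
    "sprouted": {"motif": "sprout", "deform": "bump"},
    "broken": {"motif": "exposed_face", "deform": "truncate"},
}

CATEGORIES = tuple(KernelCategory(i + 1, n) for i, n in enumerate(CATEGORY_NAMES))
_BY_NAME = {c.name: c for c in CATEGORIES}
_BY_ID = {c.id: c for c in CATEGORIES}


def category_by_name(name: str) -> KernelCategory:
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(f"unknown kernel category {name!r}; expected one of {CATEGORY_NAMES}")


def category_by_id(cid: int) -> KernelCategory:
    try:
        return _BY_ID[int(cid)]
    except KeyError:
        raise KeyError(f"unknown kernel category id {cid}; expected 1..6")


@dataclass
class KernelInstance:
    category_id: int
    center: tuple[float, float]  # (x, y) pixels
    axes: tuple[float, float]  # (a, b), a >= b > 0 (semi-axes)
    rotation: float  # radians
    z_order: int

    def __post_init__(self):
        a, b = self.axes
        if not (a >= b > 0):
            raise ValueError(f"axes must satisfy a >= b > 0, got {self.axes}")
        category_by_id(self.category_id)


@dataclass
class SceneSpec:
    image_size: tuple[int, int]  # (H, W)
    instances: list[KernelInstance]
    adhesion_level: float
    seed: int

    def __post_init__(self):
        H, W = self.image_size
        if H < 64 or W < 64:
            raise ValueError(f"image size must be at least 64x64, got {self.image_size}")
        if not (0.0 <= self.adhesion_level <= 1.0):
            raise ValueError("adhesion_level must lie in [0, 1]")


@dataclass
class InstanceAnnotation:
    category_id: int
    bbox: tuple[float, float, float, float]  # (x1, y1, x2, y2), half-open
    mask: np.ndarray  # bool (H, W), visible region only
    area: int

    def __eq__(self, other):
        return (
            isinstance(other, InstanceAnnotation)
            and self.category_id == other.category_id
            and np.allclose(self.bbox, other.bbox, atol=1e-6)
            and self.area == other.area
            and np.array_equal(self.mask, other.mask)
        )


# --------------------------------------------------------------------------
# rasterization
# --------------------------------------------------------------------------

def _instance_frame(inst: KernelInstance, H: int, W: int):
    """Per-pixel coordinates (u, v) in the kernel's own frame.

    Pixel-center-inside convention: pixel (r, c) is probed at (c+0.5, r+0.5).
    """
    ys, xs = np.mgrid[0:H, 0:W]
    px = xs + 0.5 - inst.center[0]
    py = ys + 0.5 - inst.center[1]
    c, s = math.cos(inst.rotation), math.sin(inst.rotation)
    u = c * px + s * py  # along major axis
    v = -s * px + c * py
    return u, v


def _footprint(inst: KernelInstance, H: int, W: int) -> np.ndarray:
    """Binary footprint of one kernel (before occlusion), pixel-center rule."""
    a, b = inst.axes
    u, v = _instance_frame(inst, H, W)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    deform = category_by_id(inst.category_id).appearance["deform"]
    if deform == "truncate":
        # broken kernel: chop the ellipse with a chord at 30% of the major axis
        inside &= u <= 0.3 * a
    elif deform == "bump":
        # sprouted kernel: small protrusion past one pole
        bu = u - 0.95 * a
        inside |= (bu / (0.35 * b)) ** 2 + (v / (0.3 * b)) ** 2 <= 1.0
    return inside


def _tight_bbox(mask: np.ndarray) -> tuple[float, float, float, float]:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return (float(cols[0]), float(rows[0]), float(cols[-1] + 1), float(rows[-1] + 1))


def _paint_instance(img: np.ndarray, inst: KernelInstance, footprint: np.ndarray,
                    rng: np.random.Generator) -> None:
    """Paint one kernel's full footprint (occlusion handled by paint order)."""
    H, W = footprint.shape
    a, b = inst.axes
    u, v = _instance_frame(inst, H, W)
    r2 = (u / a) ** 2 + (v / b) ** 2
    base = _BASE_COLOR + rng.normal(0.0, 8.0, size=3)
    shade = 1.0 - 0.35 * np.clip(r2, 0.0, 1.0)  # simple dome shading
    color = base[None, None, :] * shade[..., None]
    img[footprint] = color[footprint]

    motif = category_by_id(inst.category_id).appearance["motif"]
    if motif == "gray_patches":
        # gray mold adhering over much of the epidermis
        for _ in range(6):
            cu = rng.uniform(-0.7 * a, 0.7 * a)
            cv = rng.uniform(-0.7 * b, 0.7 * b)
            rad = rng.uniform(0.35, 0.6) * b
            patch = footprint & (((u - cu) ** 2 + (v - cv) ** 2) <= rad**2)
            img[patch] = np.array([140.0, 142.0, 138.0]) + rng.normal(0, 5, 3)
    elif motif == "dark_holes":
        # insect-bored holes through cortex and endosperm
        for _ in range(5):
            cu = rng.uniform(-0.75 * a, 0.75 * a)
            cv = rng.uniform(-0.6 * b, 0.6 * b)
            rad = rng.uniform(0.16, 0.26) * b + 1.0
            hole = footprint & (((u - cu) ** 2 + (v - cv) ** 2) <= rad**2)
            img[hole] = np.array([45.0, 30.0, 20.0])
    elif motif == "embryo_blotch":
        # dark brown/black disease blotch over the embryo end
        blotch = footprint & (
            ((u - 0.55 * a) / (0.6 * a)) ** 2 + (v / (0.95 * b)) ** 2 <= 1.0
        )
        img[blotch] = np.array([75.0, 45.0, 30.0]) + rng.normal(0, 4, 3)
    elif motif == "sprout":
        # pale bud breaking through the seed coat at one pole
        sprout = footprint & (u > 0.55 * a)
        img[sprout] = np.array([170.0, 215.0, 120.0]) + rng.normal(0, 3, 3)
    elif motif == "exposed_face":
        face = footprint & (u > 0.05 * a)  # endosperm face is pale
        img[face] = np.array([245.0, 235.0, 205.0]) + rng.normal(0, 4, 3)


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, list[InstanceAnnotation]]:
    """Render a scene to an RGB uint8 image and visible-region annotations.

    Occlusion: instances are painted in ascending ``z_order``; a pixel
    belongs to the highest-z instance whose footprint covers it.  Instances
    left with an empty visible mask are dropped from the annotation list.
    Bit-exactly reproducible from (spec, spec.seed).
    """
    H, W = spec.image_size
    rng = np.random.default_rng(spec.seed)
    img = np.empty((H, W, 3), dtype=np.float64)
    img[:] = _BACKGROUND + rng.normal(0.0, 4.0, size=(H, W, 3))

    order = sorted(range(len(spec.instances)), key=lambda i: (spec.instances[i].z_order, i))
    owner = np.full((H, W), -1, dtype=np.int32)
    for idx in order:
        inst = spec.instances[idx]
        inst_rng = np.random.default_rng([spec.seed, idx, inst.category_id])
        fp = _footprint(inst, H, W)
        owner[fp] = idx
        _paint_instance(img, inst, fp, inst_rng)

    annotations = []
    for idx, inst in enumerate(spec.instances):
        mask = owner == idx
        area = int(mask.sum())
        if area == 0:
            continue  # fully occluded
        annotations.append(
            InstanceAnnotation(
                category_id=inst.category_id,
                bbox=_tight_bbox(mask),
                mask=mask,
                area=area,
            )
        )
    return np.clip(img, 0, 255).astype(np.uint8), annotations


# --------------------------------------------------------------------------
# scene sampling
# --------------------------------------------------------------------------

def sample_scene(
    seed: int,
    image_size: tuple[int, int] = (512, 512),
    n_instances: int | tuple[int, int] = (10, 20),
    categories: list[str] | None = None,
    adhesion_level: float = 0.3,
    axis_range: tuple[float, float] = (18.0, 30.0),
    max_tries: int = 200,
) -> SceneSpec:
    """Sample a random dense-kernel scene specification.

    Placement uses rejection sampling on a conservative circular-separation
    rule: two kernels with major semi-axes a1, a2 may come no closer than
    ``(1 - adhesion_level) * (a1 + a2)``, so ``adhesion_level = 0``
    guarantees disjoint footprints while larger values allow progressively
    deeper partial occlusion.
    """
    rng = np.random.default_rng(seed)
    H, W = image_size
    cats = [category_by_name(c) for c in (categories or CATEGORY_NAMES)]
    if isinstance(n_instances, tuple):
        n = int(rng.integers(n_instances[0], n_instances[1] + 1))
    else:
        n = int(n_instances)
    placed: list[KernelInstance] = []
    for k in range(n):
        cat = cats[int(rng.integers(len(cats)))]
        for _ in range(max_tries):
            a = float(rng.uniform(*axis_range))
            ratio = float(rng.uniform(1.2, 2.5))
            b = a / ratio
            margin = a + 2.0
            cx = float(rng.uniform(margin, W - margin))
            cy = float(rng.uniform(margin, H - margin))
            ok = True
            for other in placed:
                d = math.hypot(cx - other.center[0], cy - other.center[1])
                if d < (1.0 - adhesion_level) * (a + other.axes[0]):
                    ok = False
                    break
            if ok:
                placed.append(
                    KernelInstance(
                        category_id=cat.id,
                        center=(cx, cy),
                        axes=(a, b),
                        rotation=float(rng.uniform(0.0, math.pi)),
                        z_order=k,
                    )
                )
                break
        # if placement failed after max_tries the kernel is skipped (scene is full)
    return SceneSpec(image_size=image_size, instances=placed,
                     adhesion_level=adhesion_level, seed=int(seed))


# --------------------------------------------------------------------------
# augmentation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentParams:
    """Magnitudes of the five augmentations (configurable defaults)."""

    brightness_factor: float = 0.6
    noise_sigma: float = 10.0  # gray levels on the 0..255 scale
    n_points: int = 50
    max_translate_frac: float = 0.15
    flip_axis: str = "horizontal"


def _reannotate(annotations: list[InstanceAnnotation]) -> list[InstanceAnnotation]:
    """Recompute bbox/area from (possibly transformed) masks; drop empties."""
    out = []
    for ann in annotations:
        area = int(ann.mask.sum())
        if area == 0:
            continue
        out.append(InstanceAnnotation(ann.category_id, _tight_bbox(ann.mask), ann.mask, area))
    return out


def augment(
    image: np.ndarray,
    annotations: list[InstanceAnnotation],
    method: str,
    seed: int,
    params: AugmentParams = AugmentParams(),
) -> tuple[np.ndarray, list[InstanceAnnotation]]:
    """Apply one of the five augmentations.

    Photometric methods (brightness, noise, points) return the annotation
    list unchanged; geometric methods (translate, flip) transform masks and
    recompute tight boxes, dropping instances pushed fully out of frame.
    """
    if method not in AUGMENT_METHODS:
        raise ValueError(f"unknown augmentation {method!r}; expected one of {AUGMENT_METHODS}")
    rng = np.random.default_rng([int(seed), AUGMENT_METHODS.index(method)])
    H, W = image.shape[:2]

    if method == "brightness":
        out = np.clip(image.astype(np.float64) * params.brightness_factor, 0, 255)
        return out.astype(np.uint8), annotations
    if method == "noise":
        out = image.astype(np.float64) + rng.normal(0.0, params.noise_sigma, image.shape)
        return np.clip(out, 0, 255).astype(np.uint8), annotations
    if method == "points":
        out = image.copy()
        ys = rng.integers(0, H, params.n_points)
        xs = rng.integers(0, W, params.n_points)
        out[ys, xs] = 255
        return out, annotations
    if method == "flip":
        out = image[:, ::-1].copy()
        flipped = [
            dataclasses.replace(a, mask=a.mask[:, ::-1].copy()) for a in annotations
        ]
        return out, _reannotate(flipped)
    # translate
    dx = int(rng.integers(-int(params.max_translate_frac * W), int(params.max_translate_frac * W) + 1))
    dy = int(rng.integers(-int(params.max_translate_frac * H), int(params.max_translate_frac * H) + 1))
    out = np.zeros_like(image)
    out[:] = np.clip(_BACKGROUND, 0, 255).astype(np.uint8)
    src_y = slice(max(0, -dy), min(H, H - dy))
    src_x = slice(max(0, -dx), min(W, W - dx))
    dst_y = slice(max(0, dy), min(H, H + dy))
    dst_x = slice(max(0, dx), min(W, W + dx))
    out[dst_y, dst_x] = image[src_y, src_x]
    moved = []
    for a in annotations:
        m = np.zeros_like(a.mask)
        m[dst_y, dst_x] = a.mask[src_y, src_x]
        moved.append(dataclasses.replace(a, mask=m))
    return out, _reannotate(moved)


# --------------------------------------------------------------------------
# dataset manifest + split
# --------------------------------------------------------------------------

PROVENANCE_TAGS = ("original",) + AUGMENT_METHODS
COMPOSITION_TAGS = CATEGORY_NAMES + ("mixture",)
SPLITS = ("train", "val", "test")


@dataclass
class DatasetRecord:
    file_name: str
    composition: str  # one of COMPOSITION_TAGS
    provenance: str  # one of PROVENANCE_TAGS
    split: str  # one of SPLITS
    spec: SceneSpec  # base scene spec (shared by the six versions)
    aug_seed: int  # seed used when provenance != "original"


@dataclass
class DatasetManifest:
    records: list[DatasetRecord] = field(default_factory=list)
    seed: int = 0

    def __len__(self):
        return len(self.records)

    def by_split(self, split: str) -> list[DatasetRecord]:
        return [r for r in self.records if r.split == split]


def split_counts(n: int) -> tuple[int, int, int]:
    """8:1:1 split of ``n`` images by largest remainder, surplus to train.

    Exact when ``n`` is divisible by 10 (e.g. 30 -> 24/3/3, 600 -> 480/60/60).
    """
    ratios = (0.8, 0.1, 0.1)
    raw = [n * r for r in ratios]
    base = [int(math.floor(x)) for x in raw]
    rem = n - sum(base)
    # distribute remainder by descending fractional part; ties favor train, then val
    order = sorted(range(3), key=lambda i: (-(raw[i] - base[i]), i))
    for i in range(rem):
        base[order[i]] += 1
    return tuple(base)


def build_dataset(
    n_single_per_class: int = 5,
    n_mixture: int = 100,
    seed: int = 0,
    image_size: tuple[int, int] = (512, 512),
    n_instances: tuple[int, int] = (10, 20),
    adhesion_level: float = 0.3,
) -> DatasetManifest:
    """Build the dataset manifest: base scenes × six versions, split 8:1:1.

    Each composition stratum holds ``n_base`` base images, each present in
    six versions (original + the five augmentations).  The split is drawn
    stratified per composition with exact 8:1:1 counts (largest-remainder
    rounding otherwise).  With the default recipe of 5 single-class bases
    per category and 100 mixture bases this yields 780 images split
    624/78/78 with 480 mixture images in train.
    """
    if n_single_per_class < 1:
        raise ValueError("n_single_per_class must be >= 1")
    if n_mixture < 0:
        raise ValueError("n_mixture must be >= 0")
    master = np.random.default_rng(seed)
    manifest = DatasetManifest(seed=int(seed))
    for comp_idx, comp in enumerate(COMPOSITION_TAGS):
        n_base = n_mixture if comp == "mixture" else n_single_per_class
        if n_base == 0:
            continue
        cats = None if comp == "mixture" else [comp]
        # build the stratum's image list: (base, provenance) in base-major order
        stratum = []
        for b in range(n_base):
            scene_seed = int(master.integers(0, 2**31 - 1))
            spec = sample_scene(
                scene_seed,
                image_size=image_size,
                n_instances=n_instances,
                categories=cats,
                adhesion_level=adhesion_level,
            )
            for prov in PROVENANCE_TAGS:
                stratum.append((b, prov, spec, scene_seed))
        n_tr, n_va, n_te = split_counts(len(stratum))
        labels = ["train"] * n_tr + ["val"] * n_va + ["test"] * n_te
        perm = master.permutation(len(stratum))
        for pos, (b, prov, spec, scene_seed) in enumerate(stratum):
            manifest.records.append(
                DatasetRecord(
                    file_name=f"{comp}_{b:04d}_{prov}.png",
                    composition=comp,
                    provenance=prov,
                    split=labels[int(perm[pos])],
                    spec=spec,
                    aug_seed=scene_seed + comp_idx + 1,
                )
            )
    return manifest


def render_record(record: DatasetRecord) -> tuple[np.ndarray, list[InstanceAnnotation]]:
    """Render one manifest record (base scene, then its augmentation if any)."""
    image, anns = render_scene(record.spec)
    if record.provenance != "original":
        image, anns = augment(image, anns, record.provenance, record.aug_seed)
    return image, anns
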