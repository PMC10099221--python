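"""Annotation I/O: COCO instance JSON (RLE masks), labelme JSON, manifests.

Masks are stored as uncompressed COCO run-length encoding: the mask is
flattened in column-major order and encoded as alternating run lengths
starting with the background run, under ``{"size": [h, w], "counts": [...]}``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from PIL import Image

from .synthetic import (
    CATEGORIES,
    DatasetManifest,
    DatasetRecord,
    InstanceAnnotation,
    KernelInstance,
    SceneSpec,
    category_by_name,
    render_record,
)

__all__ = [
    "rle_encode",
    "rle_decode",
    "write_coco",
    "read_coco",
    "read_labelme",
    "write_manifest",
    "read_manifest",
    "CocoImage",
]


# --------------------------------------------------------------------------
# RLE
# --------------------------------------------------------------------------

def rle_encode(mask: np.ndarray) -> dict:
    """Encode a binary mask as uncompressed column-major COCO RLE."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    flat = mask.flatten(order="F").astype(np.int8)
    if flat.size == 0:
        return {"size": [h, w], "counts": []}
    changes = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate([[0], changes, [flat.size]])
    counts = np.diff(bounds).tolist()
    if flat[0] == 1:  # counts must start with the background run
        counts = [0] + counts
    return {"size": [h, w], "counts": counts}


def rle_decode(rle: dict) -> np.ndarray:
    h, w = rle["size"]
    counts = rle["counts"]
    flat = np.zeros(h * w, dtype=bool)
    pos, val = 0, False
    for c in counts:
        if val:
            flat[pos : pos + c] = True
        pos += c
        val = not val
    if pos != h * w:
        raise ValueError(f"RLE length {pos} does not match size {h}x{w}")
    return flat.reshape((h, w), order="F")


# --------------------------------------------------------------------------
# COCO write / read
# --------------------------------------------------------------------------

@dataclasses.dataclass
class CocoImage:
    id: int
    file_name: str
    height: int
    width: int
    annotations: list[InstanceAnnotation]


def _coco_categories() -> list[dict]:
    return [{"id": c.id, "name": c.name, "supercategory": "kernel"} for c in CATEGORIES]


def write_coco(manifest: DatasetManifest, out_dir: str | Path,
               write_images: bool = True, progress=None) -> dict[str, Path]:
    """Render a manifest to disk as PNG images plus per-split COCO JSON.

    Returns a mapping split -> path of the annotation file written.
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    ann_dir = out_dir / "annotations"
    img_dir.mkdir(parents=True, exist_ok=True)
    ann_dir.mkdir(parents=True, exist_ok=True)

    per_split: dict[str, dict] = {
        s: {"images": [], "annotations": [], "categories": _coco_categories()}
        for s in ("train", "val", "test")
    }
    ann_id = 1
    records = manifest.records if progress is None else progress(manifest.records)
    for img_id, rec in enumerate(records, start=1):
        image, anns = render_record(rec)
        H, W = image.shape[:2]
        if write_images:
            Image.fromarray(image).save(img_dir / rec.file_name)
        doc = per_split.setdefault(
            rec.split,
            {"images": [], "annotations": [], "categories": _coco_categories()},
        )
        doc["images"].append(
            {"id": img_id, "file_name": rec.file_name, "height": H, "width": W}
        )
        for a in anns:
            x1, y1, x2, y2 = a.bbox
            doc["annotations"].append(
                {
                    "id": ann_id,
                    "image_id": img_id,
                    "category_id": a.category_id,
                    "bbox": [x1, y1, x2 - x1, y2 - y1],
                    "area": int(a.area),
                    "iscrowd": 0,
                    "segmentation": rle_encode(a.mask),
                }
            )
            ann_id += 1
    paths = {}
    for split, doc in per_split.items():
        p = ann_dir / f"instances_{split}.json"
        p.write_text(json.dumps(doc))
        paths[split] = p
    return paths


def read_coco(path: str | Path) -> list[CocoImage]:
    """Read a COCO instance-annotation file into per-image annotation lists.

    Validates the category map against the six kernel classes; polygons are
    not supported here (masks must be RLE, as written by :func:`write_coco`).
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed COCO JSON in {path}: {e}") from e
    for key in ("images", "annotations", "categories"):
        if key not in doc:
            raise ValueError(f"COCO file {path} is missing the {key!r} section")
    known = {c.id: c.name for c in CATEGORIES}
    for cat in doc["categories"]:
        if cat["id"] not in known or known[cat["id"]] != cat["name"]:
            raise ValueError(
                f"category {cat.get('name')!r} (id {cat.get('id')}) is not in the "
                f"six-kernel-class map {known}"
            )
    images = {
        im["id"]: CocoImage(im["id"], im["file_name"], im["height"], im["width"], [])
        for im in doc["images"]
    }
    for a in doc["annotations"]:
        if a["category_id"] not in known:
            raise ValueError(f"annotation {a['id']} references unknown category id {a['category_id']}")
        mask = rle_decode(a["segmentation"])
        x, y, w, h = a["bbox"]
        images[a["image_id"]].annotations.append(
            InstanceAnnotation(
                category_id=a["category_id"],
                bbox=(float(x), float(y), float(x + w), float(y + h)),
                mask=mask,
                area=int(mask.sum()),
            )
        )
    return [images[k] for k in sorted(images)]


# --------------------------------------------------------------------------
# labelme
# --------------------------------------------------------------------------

def _rasterize_polygon(points: list[list[float]], h: int, w: int) -> np.ndarray:
    """Pixel-center-inside rasterization of a polygon."""
    from matplotlib.path import Path as MplPath

    if len(points) < 3:
        raise ValueError(f"polygon needs at least 3 vertices, got {len(points)}")
    ys, xs = np.mgrid[0:h, 0:w]
    centers = np.column_stack([xs.ravel() + 0.5, ys.ravel() + 0.5])
    inside = MplPath(np.asarray(points, dtype=float)).contains_points(centers)
    return inside.reshape(h, w)


def read_labelme(path: str | Path) -> list[InstanceAnnotation]:
    """Read a labelme polygon file, rasterizing polygons to visible masks."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed labelme JSON in {path}: {e}") from e
    h, w = doc.get("imageHeight"), doc.get("imageWidth")
    if not h or not w:
        raise ValueError(f"labelme file {path} lacks imageHeight/imageWidth")
    anns = []
    for shape in doc.get("shapes", []):
        if shape.get("shape_type", "polygon") != "polygon":
            continue
        cat = category_by_name(shape["label"])
        mask = _rasterize_polygon(shape["points"], h, w)
        area = int(mask.sum())
        if area == 0:
            continue
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        anns.append(
            InstanceAnnotation(
                category_id=cat.id,
                bbox=(float(cols[0]), float(rows[0]), float(cols[-1] + 1), float(rows[-1] + 1)),
                mask=mask,
                area=area,
            )
        )
    return anns


# --------------------------------------------------------------------------
# manifest JSON round-trip
# --------------------------------------------------------------------------

def _spec_to_json(spec: SceneSpec) -> dict:
    return {
        "image_size": list(spec.image_size),
        "adhesion_level": spec.adhesion_level,
        "seed": spec.seed,
        "instances": [
            {
                "category_id": i.category_id,
                "center": list(i.center),
                "axes": list(i.axes),
                "rotation": i.rotation,
                "z_order": i.z_order,
            }
            for i in spec.instances
        ],
    }


def _spec_from_json(d: dict) -> SceneSpec:
    return SceneSpec(
        image_size=tuple(d["image_size"]),
        adhesion_level=d["adhesion_level"],
        seed=d["seed"],
        instances=[
            KernelInstance(
                category_id=i["category_id"],
                center=tuple(i["center"]),
                axes=tuple(i["axes"]),
                rotation=i["rotation"],
                z_order=i["z_order"],
            )
            for i in d["instances"]
        ],
    )


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    doc = {
        "seed": manifest.seed,
        "records": [
            {
                "file_name": r.file_name,
                "composition": r.composition,
                "provenance": r.provenance,
                "split": r.split,
                "aug_seed": r.aug_seed,
                "spec": _spec_to_json(r.spec),
            }
            for r in manifest.records
        ],
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def read_manifest(path: str | Path) -> DatasetManifest:
    doc = json.loads(Path(path).read_text())
    return DatasetManifest(
        seed=doc["seed"],
        records=[
            DatasetRecord(
                file_name=r["file_name"],
                composition=r["composition"],
                provenance=r["provenance"],
                split=r["split"],
                aug_seed=r["aug_seed"],
                spec=_spec_from_json(r["spec"]),
            )
            for r in doc["records"]
        ],
    )
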