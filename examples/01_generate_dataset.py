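"""Build the synthetic kernel dataset and inspect its stratified split.

The default recipe (5 single-class base images per category + 100 mixture
base images, each in six versions: original + five augmentations) yields
780 images split 8:1:1 into 624/78/78, with 480 mixture images in train —
the canonical composition of a small pooled-grain dataset.  Here we also
render one miniature stratum to show the per-image ground truth.
"""

from grainseg.synthetic import build_dataset, render_record

manifest = build_dataset(5, 100, seed=0)
print(f"total images: {len(manifest)}")
for split in ("train", "val", "test"):
    print(f"  {split}: {len(manifest.by_split(split))}")
mixture_train = sum(
    1 for r in manifest.records if r.composition == "mixture" and r.split == "train"
)
print(f"  mixture images in train: {mixture_train}")

# render a tiny manifest to look at actual annotations
small = build_dataset(1, 0, seed=7, image_size=(128, 128), n_instances=(3, 5))
rec = small.records[0]
image, anns = render_record(rec)
print(f"\nrendered {rec.file_name}: {image.shape[1]}x{image.shape[0]} px, "
      f"{len(anns)} visible instances")
for a in anns:
    print(f"  class {a.category_id}  bbox {tuple(round(v, 1) for v in a.bbox)}  "
          f"visible area {a.area} px")
# Masks cover only visible pixels: occluded parts of a kernel are unlabeled,
# and a fully hidden kernel produces no annotation at all.
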