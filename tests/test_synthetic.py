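"""Scene rendering, occlusion resolution, augmentations, dataset split."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grainseg import synthetic
from grainseg.synthetic import (
    AUGMENT_METHODS,
    CATEGORY_NAMES,
    KernelInstance,
    SceneSpec,
    augment,
    build_dataset,
    category_by_id,
    category_by_name,
    render_scene,
    sample_scene,
    split_counts,
)


def _ellipse(cid=1, center=(40.0, 40.0), axes=(14.0, 8.0), rot=0.3, z=0):
    return KernelInstance(category_id=cid, center=center, axes=axes, rotation=rot, z_order=z)


def _brute_force_ellipse_area(inst, H, W):
    """Pixel-center-inside rasterization by explicit per-pixel loop."""
    n = 0
    c, s = math.cos(inst.rotation), math.sin(inst.rotation)
    a, b = inst.axes
    for r in range(H):
        for col in range(W):
            px, py = col + 0.5 - inst.center[0], r + 0.5 - inst.center[1]
            u, v = c * px + s * py, -s * px + c * py
            if (u / a) ** 2 + (v / b) ** 2 <= 1.0:
                n += 1
    return n


class TestCategories:
    def test_ids_biject_onto_names(self):
        assert [category_by_name(n).id for n in CATEGORY_NAMES] == [1, 2, 3, 4, 5, 6]
        assert [category_by_id(i).name for i in range(1, 7)] == list(CATEGORY_NAMES)
        with pytest.raises(KeyError):
            category_by_name("brokenish")
        with pytest.raises(KeyError):
            category_by_id(7)


class TestRenderScene:
    def test_single_instance_mask_equals_rasterized_ellipse(self):
        inst = _ellipse()
        spec = SceneSpec((80, 80), [inst], adhesion_level=0.0, seed=3)
        _, anns = render_scene(spec)
        assert len(anns) == 1
        assert anns[0].area == _brute_force_ellipse_area(inst, 80, 80)

    def test_total_occlusion_drops_hidden_instance(self):
        a = _ellipse(z=1)
        b = _ellipse(z=2)
        spec = SceneSpec((80, 80), [a, b], adhesion_level=1.0, seed=0)
        _, anns = render_scene(spec)
        assert len(anns) == 1

    def test_partial_overlap_masks_disjoint_and_union_preserved(self):
        lo = _ellipse(center=(40.0, 40.0), z=1)
        hi = _ellipse(cid=2, center=(48.0, 40.0), z=2)
        spec = SceneSpec((80, 80), [lo, hi], adhesion_level=1.0, seed=0)
        _, anns = render_scene(spec)
        assert len(anns) == 2
        m1, m2 = anns[0].mask, anns[1].mask
        assert not (m1 & m2).any()
        fp_lo = synthetic._footprint(lo, 80, 80)
        fp_hi = synthetic._footprint(hi, 80, 80)
        assert np.array_equal(m1 | m2, fp_lo | fp_hi)
        # the higher-z instance keeps its full footprint
        assert np.array_equal(m2, fp_hi)

    def test_bbox_is_tight_box_of_mask(self, easy_scene):
        _, _, anns = easy_scene
        for a in anns:
            rows = np.flatnonzero(a.mask.any(axis=1))
            cols = np.flatnonzero(a.mask.any(axis=0))
            assert a.bbox == (cols[0], rows[0], cols[-1] + 1, rows[-1] + 1)
            assert a.area == a.mask.sum() > 0

    def test_deterministic_given_seed(self, easy_scene):
        spec, image, anns = easy_scene
        image2, anns2 = render_scene(spec)
        assert np.array_equal(image, image2)
        assert anns == anns2

    def test_rejects_small_canvas_and_allows_empty_scene(self):
        with pytest.raises(ValueError):
            SceneSpec((32, 128), [], adhesion_level=0.0, seed=0)
        img, anns = render_scene(SceneSpec((64, 64), [], adhesion_level=0.0, seed=0))
        assert img.shape == (64, 64, 3) and anns == []


class TestSampleScene:
    def test_zero_adhesion_yields_disjoint_footprints(self):
        spec = sample_scene(5, image_size=(256, 256), n_instances=8, adhesion_level=0.0)
        _, anns = render_scene(spec)
        # with no occlusion every mask is the full footprint, so areas are intact
        total = np.zeros((256, 256), bool)
        for a in anns:
            assert not (total & a.mask).any()
            total |= a.mask

    def test_broken_kernels_may_violate_ellipticity_others_do_not(self):
        spec = sample_scene(11, image_size=(192, 192), n_instances=6,
                            categories=["broken"], adhesion_level=0.0)
        _, anns = render_scene(spec)
        for inst, a in zip(spec.instances, anns):
            assert a.area < _brute_force_ellipse_area(inst, 192, 192)


class TestAugment:
    def test_flip_is_an_involution(self, easy_scene):
        _, image, anns = easy_scene
        once = augment(image, anns, "flip", seed=1)
        twice = augment(*once, "flip", seed=1)
        assert np.array_equal(twice[0], image)
        assert twice[1] == anns

    @pytest.mark.parametrize("method", ["brightness", "noise", "points"])
    def test_photometric_methods_leave_annotations_unchanged(self, easy_scene, method):
        _, image, anns = easy_scene
        out_img, out_anns = augment(image, anns, method, seed=2)
        assert out_anns is anns
        assert out_img.shape == image.shape

    def test_translate_shifts_boxes_exactly(self, easy_scene):
        _, image, anns = easy_scene
        out_img, out_anns = augment(image, anns, "translate", seed=3)
        assert out_anns
        # every output bbox must be the tight box of its shifted mask
        for a in out_anns:
            rows = np.flatnonzero(a.mask.any(axis=1))
            cols = np.flatnonzero(a.mask.any(axis=0))
            assert a.bbox == (cols[0], rows[0], cols[-1] + 1, rows[-1] + 1)

    def test_translate_interior_instances_shift_by_exact_offset(self):
        inst = _ellipse(center=(64.0, 64.0))
        spec = SceneSpec((128, 128), [inst], adhesion_level=0.0, seed=1)
        image, anns = render_scene(spec)
        out_img, out_anns = augment(image, anns, "translate", seed=5)
        rng = np.random.default_rng([5, AUGMENT_METHODS.index("translate")])
        dx = int(rng.integers(-19, 20))
        dy = int(rng.integers(-19, 20))
        (x1, y1, x2, y2) = anns[0].bbox
        assert out_anns[0].bbox == (x1 + dx, y1 + dy, x2 + dx, y2 + dy)

    def test_unknown_method_rejected(self, easy_scene):
        _, image, anns = easy_scene
        with pytest.raises(ValueError, match="unknown augmentation"):
            augment(image, anns, "rotate", seed=0)


class TestSplit:
    @given(st.integers(min_value=1, max_value=5000))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_split_counts_sum_and_ratio(self, n):
        tr, va, te = split_counts(n)
        assert tr + va + te == n
        assert abs(tr - 0.8 * n) < 1 + 1e-9
        assert abs(va - 0.1 * n) < 1 + 1e-9
        assert abs(te - 0.1 * n) < 1 + 1e-9
        assert tr >= va >= 0 and te >= 0

    def test_default_recipe_reproduces_reference_distribution(self):
        manifest = build_dataset(5, 100, seed=0)
        assert len(manifest) == 780
        counts = {s: len(manifest.by_split(s)) for s in ("train", "val", "test")}
        assert counts == {"train": 624, "val": 78, "test": 78}
        mix = [r for r in manifest.records if r.composition == "mixture"]
        assert sum(r.split == "train" for r in mix) == 480
        assert sum(r.split == "val" for r in mix) == 60
        for comp in CATEGORY_NAMES:
            comp_recs = [r for r in manifest.records if r.composition == comp]
            assert len(comp_recs) == 30
            assert sum(r.split == "train" for r in comp_recs) == 24
            assert sum(r.split == "val" for r in comp_recs) == 3
            assert sum(r.split == "test" for r in comp_recs) == 3

    def test_every_base_image_has_six_versions(self):
        manifest = build_dataset(1, 2, seed=1)
        assert len(manifest) == (6 + 2) * 6
        from collections import Counter

        groups = Counter((r.composition, r.file_name.split("_")[-2]) for r in manifest.records)
        assert set(groups.values()) == {6}

    def test_minimal_recipe_arithmetic(self):
        assert len(build_dataset(1, 0, seed=0)) == 36

    def test_manifest_is_deterministic_in_seed(self):
        a = build_dataset(1, 1, seed=42)
        b = build_dataset(1, 1, seed=42)
        assert [dataclasses.asdict(r) for r in a.records] == [
            dataclasses.asdict(r) for r in b.records
        ]

    def test_invalid_recipe_rejected(self):
        with pytest.raises(ValueError):
            build_dataset(0, 5)
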