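"""CutMix / Mosaic / GridMask: label arithmetic, preservation guarantees,
pixel provenance, determinism."""

import numpy as np
import pytest

from phytofuse.augment import (GridMaskSpec, MixResult, build_grid_mask,
                               cutmix, gridmask, mosaic, one_hot)
from phytofuse.syndata import LabeledImage, generate_dataset


def solid_image(value, class_id, h=10, w=10, boxes=None, image_id="img"):
    px = np.full((h, w, 3), value, dtype=np.uint8)
    return LabeledImage(pixels=px, class_id=class_id,
                        boxes=boxes if boxes is not None else [(1, 1, 3, 3)],
                        image_id=image_id)


class TestCutMix:
    def test_label_mixing_formula(self):
        # lam = 0.7 with one-hot labels -> [0.7, 0.3, 0, 0, 0]
        y = 0.7 * one_hot(0) + (1 - 0.7) * one_hot(1)
        assert np.allclose(y, [0.7, 0.3, 0, 0, 0])
        # and the operator respects it: realized-lam mixing in region mode
        a = solid_image(10, 0, boxes=[(0, 0, 1, 1)])
        b = solid_image(200, 1, boxes=[(9, 9, 10, 10)])
        res = cutmix(a, b, preserve_lesions=False, seed=3)
        assert np.allclose(res.label,
                           res.lam * one_hot(0) + (1 - res.lam) * one_hot(1))

    def test_region_lam_equals_retained_fraction(self):
        for seed in range(10):
            a = solid_image(10, 0, boxes=[(0, 0, 1, 1)])
            b = solid_image(200, 1, boxes=[(9, 9, 10, 10)])
            res = cutmix(a, b, preserve_lesions=False, seed=seed)
            retained = np.mean(np.all(res.pixels == 10, axis=-1))
            assert res.lam == pytest.approx(retained)

    def test_explicit_area_arithmetic(self):
        # a 5x4 paste on 10x10 -> lam = 1 - 20/100 = 0.8
        a = solid_image(10, 0, boxes=[(0, 0, 1, 1)])
        b = solid_image(200, 1, boxes=[(0, 0, 1, 1)])
        # find a seed producing any paste, then verify counted pixels = 1-lam
        res = cutmix(a, b, preserve_lesions=False, seed=0)
        n_replaced = int(np.sum(np.all(res.pixels == 200, axis=-1)))
        assert res.lam == pytest.approx(1 - n_replaced / 100)

    def test_zero_area_paste_is_identity(self):
        a = solid_image(10, 0)
        b = solid_image(200, 1)
        # beta_alpha tiny -> lam ~ {0 or 1}; search a seed with lam=1 cut
        found = False
        for seed in range(50):
            res = cutmix(a, b, beta_alpha=0.05, preserve_lesions=False,
                         seed=seed)
            if res.lam == 1.0:
                assert np.array_equal(res.pixels, a.pixels)
                assert np.array_equal(res.label, one_hot(0))
                found = True
                break
        assert found

    def test_blend_mode_formula(self):
        a = solid_image(100, 0)
        b = solid_image(200, 1)
        res = cutmix(a, b, mode="blend", seed=4)
        expected = np.rint(res.lam * 100 + (1 - res.lam) * 200)
        assert np.allclose(res.pixels, expected)

    def test_preservation_keeps_a_lesions_intact(self):
        rng = np.random.default_rng(0)
        samples, _ = generate_dataset(2, seed=31)
        for seed in range(8):
            i, j = rng.integers(0, len(samples), 2)
            a, b = samples[i].image, samples[j].image
            res = cutmix(a, b, preserve_lesions=True, seed=seed)
            if res.lam == 1.0:
                continue  # fallback no-op
            for (x0, y0, x1, y1) in a.boxes:
                assert np.array_equal(res.pixels[y0:y1, x0:x1],
                                      a.pixels[y0:y1, x0:x1])

    def test_preservation_never_truncates_b_lesion(self):
        samples, _ = generate_dataset(2, seed=32)
        a, b = samples[0].image, samples[6].image
        res = cutmix(a, b, preserve_lesions=True, seed=5)
        # every surviving box is either an a-box or a full b-box
        for bx in res.boxes:
            assert bx in a.boxes or bx in b.boxes

    def test_infeasible_preservation_falls_back(self):
        # lesion covers the whole of a -> no admissible paste rectangle
        a = solid_image(10, 0, boxes=[(0, 0, 10, 10)])
        b = solid_image(200, 1, boxes=[(0, 0, 10, 10)])
        res = cutmix(a, b, beta_alpha=100.0, preserve_lesions=True, seed=1)
        assert res.lam == 1.0
        assert np.array_equal(res.pixels, a.pixels)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError, match="size"):
            cutmix(solid_image(1, 0, h=8, w=8), solid_image(1, 1, h=10, w=10))

    def test_determinism(self):
        a = solid_image(10, 0)
        b = solid_image(200, 1)
        r1 = cutmix(a, b, seed=9, preserve_lesions=False)
        r2 = cutmix(a, b, seed=9, preserve_lesions=False)
        assert np.array_equal(r1.pixels, r2.pixels) and r1.lam == r2.lam


class TestMosaic:
    def four(self):
        return [solid_image(v, c, h=2, w=2, boxes=[(0, 0, 2, 2)],
                            image_id=f"i{c}")
                for c, v in enumerate([10, 60, 120, 240])]

    def test_quadrant_placement(self):
        res = mosaic(self.four(), canvas=(4, 4), split=(2, 2))
        assert np.all(res.pixels[:2, :2] == 10)     # 1: top-left
        assert np.all(res.pixels[:2, 2:] == 60)     # 2: top-right
        assert np.all(res.pixels[2:, :2] == 120)    # 3: bottom-left
        assert np.all(res.pixels[2:, 2:] == 240)    # 4: bottom-right

    def test_identical_inputs_keep_label(self):
        imgs = [solid_image(50, 2, h=4, w=4) for _ in range(4)]
        res = mosaic(imgs, canvas=(8, 8), split=(4, 4))
        assert np.allclose(res.label, one_hot(2))

    def test_area_weights_split_1_1(self):
        imgs = [solid_image(v, c, h=4, w=4) for c, v in
                enumerate([10, 60, 120, 240])]
        res = mosaic(imgs, canvas=(4, 4), split=(1, 1))
        assert np.allclose(res.label, [1 / 16, 3 / 16, 3 / 16, 9 / 16, 0])

    def test_label_sums_to_one(self):
        for seed in range(5):
            res = mosaic(self.four(), canvas=(6, 6), split="random", seed=seed)
            assert res.label.sum() == pytest.approx(1.0, abs=1e-9)

    def test_pixel_conservation(self):
        # nearest-neighbour resize: every output pixel is some input pixel
        samples, _ = generate_dataset(1, seed=41)
        imgs = [samples[i].image for i in range(4)]
        res = mosaic(imgs, canvas=(64, 64), split="random", seed=2)
        allowed = np.unique(np.concatenate(
            [im.pixels.reshape(-1, 3) for im in imgs]), axis=0)
        out = np.unique(res.pixels.reshape(-1, 3), axis=0)
        allowed_set = {tuple(r) for r in allowed}
        assert all(tuple(r) in allowed_set for r in out)

    def test_boxes_remapped_into_quadrants(self):
        res = mosaic(self.four(), canvas=(8, 8), split=(4, 4))
        assert len(res.boxes) == 4
        quads = [(0, 0, 4, 4), (4, 0, 8, 4), (0, 4, 4, 8), (4, 4, 8, 8)]
        for bx, (qx0, qy0, qx1, qy1) in zip(res.boxes, quads):
            assert qx0 <= bx[0] < bx[2] <= qx1
            assert qy0 <= bx[1] < bx[3] <= qy1

    def test_degenerate_split_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            mosaic(self.four(), canvas=(4, 4), split=(0, 2))

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError, match="4 images"):
            mosaic(self.four()[:3], canvas=(4, 4))


class TestGridMask:
    def test_identity_mask(self):
        img = solid_image(77, 1)
        spec = GridMaskSpec(unit=4, ratio=0.5, offset=(0, 0),
                            mask=np.ones((10, 10), dtype=np.uint8))
        out = gridmask(img, spec, preserve_lesions=False)
        assert np.array_equal(out.pixels, img.pixels)

    def test_forced_exemption_with_zero_mask(self):
        img = solid_image(77, 1, boxes=[(2, 3, 5, 6)])
        spec = GridMaskSpec(unit=4, ratio=0.5, offset=(0, 0),
                            mask=np.zeros((10, 10), dtype=np.uint8))
        out = gridmask(img, spec, preserve_lesions=True)
        survived = np.any(out.pixels > 0, axis=-1)
        expected = np.zeros((10, 10), dtype=bool)
        expected[3:6, 2:5] = True
        assert np.array_equal(survived, expected)

    def test_analytic_grid_fraction(self):
        # unit=4, ratio=0.5 -> drop side round(4*sqrt(0.5)) = 3 -> 9/16 zeroed
        spec = GridMaskSpec(unit=4, ratio=0.5, offset=(0, 0))
        mask = build_grid_mask(8, 8, spec)
        zeroed = 1 - mask.mean()
        # enumerate cells: each 4x4 cell drops a 3x3 block
        assert zeroed == pytest.approx(9 / 16)
        assert mask.mean() == pytest.approx(spec.kept_fraction)

    def test_mask_mean_close_to_analytic(self):
        # invariant for images >= 4 grid periods wide
        for unit, ratio in [(8, 0.4), (10, 0.55), (16, 0.3)]:
            spec = GridMaskSpec(unit=unit, ratio=ratio, offset=(0, 0))
            mask = build_grid_mask(4 * unit, 4 * unit, spec)
            assert abs(mask.mean() - spec.kept_fraction) <= 0.05

    def test_label_and_boxes_unchanged(self):
        img = solid_image(50, 3, boxes=[(1, 1, 4, 4)])
        out = gridmask(img, "random", seed=7)
        assert out.class_id == 3 and out.boxes == [(1, 1, 4, 4)]

    def test_preserved_pixels_identical_to_source(self):
        samples, _ = generate_dataset(2, seed=51)
        for s in samples:
            out = gridmask(s.image, "random", preserve_lesions=True, seed=3)
            for (x0, y0, x1, y1) in s.image.boxes:
                assert np.array_equal(out.pixels[y0:y1, x0:x1],
                                      s.image.pixels[y0:y1, x0:x1])

    def test_determinism(self):
        img = solid_image(90, 0)
        a = gridmask(img, "random", seed=13)
        b = gridmask(img, "random", seed=13)
        assert np.array_equal(a.pixels, b.pixels)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            GridMaskSpec(unit=1, ratio=0.5, offset=(0, 0))
        with pytest.raises(ValueError):
            GridMaskSpec(unit=4, ratio=1.0, offset=(0, 0))


class TestMixResultInvariants:
    def test_label_must_be_probability_vector(self):
        with pytest.raises(ValueError):
            MixResult(pixels=np.zeros((2, 2, 3), dtype=np.uint8),
                      label=np.array([0.5, 0.2, 0, 0, 0]), boxes=[],
                      lam=0.5, source_ids=("a", "b"))

    def test_lam_bounds(self):
        with pytest.raises(ValueError):
            MixResult(pixels=np.zeros((2, 2, 3), dtype=np.uint8),
                      label=one_hot(0), boxes=[], lam=1.2,
                      source_ids=("a", "b"))
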