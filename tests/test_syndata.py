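"""Synthetic data generator: invariants, planted-ambiguity bounds, disk IO."""

import json

import numpy as np
import pandas as pd
import pytest

from phytofuse import syndata
from phytofuse.syndata import (AMBIGUOUS_PROFILE, AMBIGUOUS_STYLE, CHANNELS,
                               CLASS_NAMES, DISEASE_CLASSES, LESION_STYLES,
                               DatasetValidationError, SensorWindow,
                               bayes_accuracy, bayes_image_predict,
                               bayes_joint_predict, bayes_sensor_predict,
                               box_to_coco, coco_to_box, generate_dataset,
                               read_dataset, write_dataset,
                               _leaf_background, _mask_bbox, _render_lesion)


class TestClassTable:
    def test_exactly_five_classes_fixed_names(self):
        assert CLASS_NAMES == ("brown_spot", "brown_stripe", "fusarium_wilt",
                               "leaf_mold", "bacterial_leaf_spot")
        assert len(DISEASE_CLASSES) == 5

    def test_styles_bijective(self):
        styles = [c.lesion_style for c in DISEASE_CLASSES]
        assert len(set(styles)) == 5
        assert tuple(styles) == LESION_STYLES

    def test_humid_regime_for_fungal_classes(self):
        # leaf_mold and fusarium_wilt draw humidity from a high regime
        for c in DISEASE_CLASSES:
            mu = c.sensor_profile["humidity"][0]
            if c.name in ("leaf_mold", "fusarium_wilt"):
                assert mu > 80
            else:
                assert mu < 80


class TestGenerateDataset:
    def test_counts_and_invariants(self, small_dataset):
        samples, _ = small_dataset
        assert len(samples) == 10
        for s in samples:
            s.validate()
            assert len(s.image.boxes) >= 1
            hum = s.sensors.readings[CHANNELS.index("humidity")]
            assert hum.min() >= 0 and hum.max() <= 100
            assert s.sensors.readings.shape == (4, 24)

    def test_class_balance_exact(self):
        samples, _ = generate_dataset(3, seed=1)
        counts = np.bincount([s.class_id for s in samples], minlength=5)
        assert (counts == 3).all()

    def test_determinism_byte_identical(self):
        a, _ = generate_dataset(2, seed=5, confusability=0.3)
        b, _ = generate_dataset(2, seed=5, confusability=0.3)
        for x, y in zip(a, b):
            assert np.array_equal(x.image.pixels, y.image.pixels)
            assert np.array_equal(x.sensors.readings, y.sensors.readings)
            assert x.meta == y.meta

    def test_seed_changes_output(self):
        a, _ = generate_dataset(1, seed=1)
        b, _ = generate_dataset(1, seed=2)
        assert not np.array_equal(a[0].image.pixels, b[0].image.pixels)

    @pytest.mark.parametrize("kwargs", [
        {"n_per_class": 0}, {"n_per_class": 2, "image_size": (32, 64)},
        {"n_per_class": 2, "window_hours": 0},
        {"n_per_class": 2, "confusability": 1.5},
    ])
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(ValueError):
            generate_dataset(**kwargs)


class TestLesionRendering:
    @pytest.mark.parametrize("style", list(LESION_STYLES) + [AMBIGUOUS_STYLE])
    def test_all_rendered_pixels_inside_box(self, style):
        rng = np.random.default_rng(hash(style) % (2 ** 31))
        for _ in range(5):
            bg = _leaf_background(64, 64, rng)
            before = bg.copy()
            mask = _render_lesion(bg, style, rng)
            changed = np.any(bg != before, axis=-1)
            assert changed.any(), "lesion rendered nothing"
            assert (changed <= mask).all(), "pixels changed outside the mask"
            x0, y0, x1, y1 = _mask_bbox(mask)
            box_cover = np.zeros((64, 64), dtype=bool)
            box_cover[y0:y1, x0:x1] = True
            assert (mask <= box_cover).all(), "mask escapes its bounding box"


class TestPlantedAmbiguity:
    def test_confusability_zero_image_rule_perfect(self, small_dataset):
        samples, _ = small_dataset
        assert bayes_accuracy(samples, bayes_image_predict) == 1.0
        assert bayes_accuracy(samples, bayes_sensor_predict) == 1.0

    def test_image_bayes_bound_full_confusability(self):
        # c=1: image-only Bayes accuracy = 1 - 1*(2/5)*(1/2) = 0.80
        samples, _ = generate_dataset(200, seed=3, confusability=1.0)
        acc = bayes_accuracy(samples, bayes_image_predict)
        se = np.sqrt(0.8 * 0.2 / 1000)
        assert 0.80 - 3 * se <= acc <= 0.80 + 3 * se

    def test_sensor_bayes_bound(self):
        samples, _ = generate_dataset(200, seed=13, confusability=0.5)
        acc = bayes_accuracy(samples, bayes_sensor_predict)
        expected = 1 - 0.5 / 5
        se = np.sqrt(expected * (1 - expected) / 1000)
        assert abs(acc - expected) <= 3 * se

    def test_joint_bayes_near_perfect(self):
        samples, _ = generate_dataset(100, seed=4, confusability=1.0)
        assert bayes_accuracy(samples, bayes_joint_predict) >= 0.99

    def test_ambiguity_is_modality_exclusive(self):
        samples, _ = generate_dataset(50, seed=9, confusability=1.0)
        for s in samples:
            assert not (s.meta["image_ambiguous"] and s.meta["sensor_ambiguous"])
            if s.meta["image_ambiguous"]:
                assert s.class_id in syndata.IMAGE_AMBIGUOUS_CLASSES
            if s.meta["sensor_ambiguous"]:
                assert s.class_id in syndata.SENSOR_AMBIGUOUS_CLASSES


class TestCocoConversion:
    def test_hand_case(self):
        assert box_to_coco((4, 5, 14, 25)) == [4, 5, 10, 20]

    def test_roundtrip(self):
        for box in [(0, 0, 3, 3), (4, 5, 14, 25), (10, 20, 11, 21)]:
            assert coco_to_box(box_to_coco(box)) == box


class TestDiskIO:
    def test_write_then_read_identity(self, small_dataset, tmp_path):
        samples, _ = small_dataset
        write_dataset(samples, tmp_path / "ds")
        back = read_dataset(tmp_path / "ds")
        by_id = {s.image.image_id: s for s in back}
        assert len(back) == len(samples)
        for s in samples:
            r = by_id[s.image.image_id]
            assert r.class_id == s.class_id
            assert r.image.boxes == s.image.boxes
            assert np.array_equal(r.image.pixels, s.image.pixels)
            assert np.array_equal(r.sensors.readings, s.sensors.readings)

    def test_categories_array(self, small_dataset, tmp_path):
        samples, _ = small_dataset
        write_dataset(samples, tmp_path / "ds")
        coco = json.loads((tmp_path / "ds" / "annotations.json").read_text())
        assert len(coco["categories"]) == 5

    def test_write_deterministic_bytes(self, small_dataset, tmp_path):
        samples, _ = small_dataset
        write_dataset(samples, tmp_path / "a")
        write_dataset(samples, tmp_path / "b")
        assert (tmp_path / "a" / "sensors.csv").read_bytes() == \
            (tmp_path / "b" / "sensors.csv").read_bytes()
        name = samples[0].image.image_id + ".png"
        assert (tmp_path / "a" / "images" / name).read_bytes() == \
            (tmp_path / "b" / "images" / name).read_bytes()

    def test_empty_samples_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_dataset([], tmp_path / "ds")

    def test_missing_annotation_file(self, tmp_path):
        (tmp_path / "ds").mkdir()
        with pytest.raises(FileNotFoundError, match="annotation"):
            read_dataset(tmp_path / "ds")

    def test_annotation_referencing_missing_image(self, small_dataset, tmp_path):
        samples, _ = small_dataset
        out = write_dataset(samples, tmp_path / "ds")
        coco = json.loads((out / "annotations.json").read_text())
        coco["annotations"][0]["image_id"] = "ghost_image"
        (out / "annotations.json").write_text(json.dumps(coco))
        with pytest.raises(DatasetValidationError, match="ghost_image"):
            read_dataset(out)

    def test_out_of_range_humidity_rejected(self, small_dataset, tmp_path):
        samples, _ = small_dataset
        out = write_dataset(samples, tmp_path / "ds")
        df = pd.read_csv(out / "sensors.csv")
        df.loc[df[df.channel == "humidity"].index[0], "value"] = 120.0
        df.to_csv(out / "sensors.csv", index=False)
        with pytest.raises(DatasetValidationError, match="humidity"):
            read_dataset(out)


class TestSensorWindowValidation:
    def test_humidity_bounds(self):
        readings = np.zeros((4, 24))
        readings[CHANNELS.index("humidity")] = 120.0
        with pytest.raises(DatasetValidationError, match="humidity"):
            SensorWindow(readings=readings).validate()

    def test_hour_count_mismatch(self):
        with pytest.raises(DatasetValidationError):
            SensorWindow(readings=np.zeros((4, 12)), window_hours=24).validate()


class TestMultiLesion:
    def test_multi_lesion_mode(self):
        samples, _ = generate_dataset(2, seed=21, multi_lesion=True)
        counts = [len(s.image.boxes) for s in samples]
        assert all(1 <= c <= 3 for c in counts)
        assert any(c > 1 for c in counts)
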