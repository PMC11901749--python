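"""Synthetic multimodal dataset generator.

Produces leaf images with class-specific parametric lesions (plus tight
bounding boxes) and class-conditional hourly environmental sensor windows
(temperature, humidity, light, CO2).  Two ambiguities are planted with a
controllable rate `confusability` c:

* a fraction c of ``brown_spot`` and ``bacterial_leaf_spot`` images are
  rendered with one shared lesion appearance, so pixels alone cannot
  separate that pair (the sensor window can);
* a fraction c of ``fusarium_wilt`` and ``leaf_mold`` samples draw their
  sensor window from one shared profile, so sensors alone cannot separate
  that pair (the lesion appearance can).

With balanced classes the Bayes-optimal accuracy of either single modality
is therefore 1 - c * (2/5) * (1/2) = 1 - c/5, while both modalities jointly
identify every sample.  The latent assignments are recorded per sample so
tests can evaluate the exact Bayes rules.

Lesions are parametric shapes (ellipses, streaks, noise-textured patches)
on a green leaf-like background — chosen for analytic control, not realism.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger(__name__)

CHANNELS: Tuple[str, ...] = ("temperature", "humidity", "light", "co2")

CLASS_NAMES: Tuple[str, ...] = (
    "brown_spot", "brown_stripe", "fusarium_wilt", "leaf_mold",
    "bacterial_leaf_spot",
)

LESION_STYLES: Tuple[str, ...] = (
    "round-sharp-border", "elongated-streak", "white-patch",
    "yellow-to-gray-patch", "wet-blurred-halo",
)

#: shared appearance used for the planted image ambiguity (classes 0 and 4)
AMBIGUOUS_STYLE = "ambiguous-round"
#: shared sensor profile used for the planted sensor ambiguity (classes 2 and 3)
AMBIGUOUS_PROFILE = "ambiguous-humid"

IMAGE_AMBIGUOUS_CLASSES = (0, 4)
SENSOR_AMBIGUOUS_CLASSES = (2, 3)

# per-channel (mean, sd); humidity regimes: moderate for classes 0/1/4,
# high for the humidity-linked fungal classes 2/3 (and the shared profile)
SENSOR_PROFILES: Dict[str, Dict[str, Tuple[float, float]]] = {
    "brown_spot":          {"temperature": (22.0, 0.8), "humidity": (55.0, 3.0),
                            "light": (500.0, 25.0), "co2": (400.0, 15.0)},
    "brown_stripe":        {"temperature": (30.0, 0.8), "humidity": (60.0, 3.0),
                            "light": (700.0, 25.0), "co2": (520.0, 15.0)},
    "fusarium_wilt":       {"temperature": (18.0, 0.8), "humidity": (86.0, 2.5),
                            "light": (300.0, 25.0), "co2": (460.0, 15.0)},
    "leaf_mold":           {"temperature": (30.0, 0.8), "humidity": (89.0, 2.5),
                            "light": (350.0, 25.0), "co2": (640.0, 15.0)},
    "bacterial_leaf_spot": {"temperature": (26.0, 0.8), "humidity": (70.0, 3.0),
                            "light": (600.0, 25.0), "co2": (580.0, 15.0)},
    AMBIGUOUS_PROFILE:     {"temperature": (24.0, 0.8), "humidity": (87.0, 2.5),
                            "light": (325.0, 25.0), "co2": (550.0, 15.0)},
}

_STYLE_TO_CLASS = {s: i for i, s in enumerate(LESION_STYLES)}
_PROFILE_TO_CLASS = {n: i for i, n in enumerate(CLASS_NAMES)}

_LESION_COLORS: Dict[str, Tuple[float, float, float]] = {
    "round-sharp-border": (152.0, 76.0, 22.0),
    "elongated-streak": (118.0, 58.0, 30.0),
    "white-patch": (235.0, 234.0, 224.0),
    "yellow-to-gray-patch": (202.0, 182.0, 62.0),
    "wet-blurred-halo": (38.0, 44.0, 58.0),
    AMBIGUOUS_STYLE: (104.0, 52.0, 78.0),
}


class DatasetValidationError(ValueError):
    """Raised when an on-disk dataset violates a structural invariant."""


@dataclass(frozen=True)
class DiseaseClass:
    id: int
    name: str
    lesion_style: str
    sensor_profile: Dict[str, Tuple[float, float]]


DISEASE_CLASSES: Tuple[DiseaseClass, ...] = tuple(
    DiseaseClass(i, name, LESION_STYLES[i], SENSOR_PROFILES[name])
    for i, name in enumerate(CLASS_NAMES)
)


@dataclass
class LabeledImage:
    pixels: np.ndarray          # H x W x 3, uint8
    class_id: int
    boxes: List[Tuple[int, int, int, int]]  # (x0, y0, x1, y1), 0-based, half-open
    image_id: str

    def validate(self) -> None:
        h, w = self.pixels.shape[:2]
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise DatasetValidationError(f"{self.image_id}: pixels must be HxWx3")
        for b in self.boxes:
            x0, y0, x1, y1 = b
            if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
                raise DatasetValidationError(
                    f"{self.image_id}: box {b} outside image {w}x{h}")


@dataclass
class SensorWindow:
    readings: np.ndarray        # C_s x T, float
    channel_names: Tuple[str, ...] = CHANNELS
    window_hours: int = 24

    def validate(self) -> None:
        c, t = self.readings.shape
        if c != len(self.channel_names):
            raise DatasetValidationError("channel count mismatch")
        if t != self.window_hours:
            raise DatasetValidationError(
                f"expected {self.window_hours} hourly readings, got {t}")
        hum = self.readings[self.channel_names.index("humidity")]
        if (hum < 0).any() or (hum > 100).any():
            raise DatasetValidationError(
                f"humidity outside [0, 100]: {hum.min():.2f}..{hum.max():.2f}")


@dataclass
class MultimodalSample:
    image: LabeledImage
    sensors: SensorWindow
    class_id: int
    meta: Dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.image.class_id != self.class_id:
            raise DatasetValidationError(
                f"{self.image.image_id}: image class {self.image.class_id} "
                f"!= sample class {self.class_id}")
        self.image.validate()
        self.sensors.validate()


# --------------------------------------------------------------- lesion draw

def _grid(h: int, w: int):
    return np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float),
                       indexing="ij")


def _ellipse_mask(h, w, cy, cx, ry, rx, theta=0.0):
    yy, xx = _grid(h, w)
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = (dx * ct + dy * st) / rx
    v = (-dx * st + dy * ct) / ry
    return u * u + v * v <= 1.0


def _render_lesion(canvas: np.ndarray, style: str,
                   rng: np.random.Generator) -> np.ndarray:
    """Draw one lesion of `style` in-place; return its boolean mask.

    Only pixels inside the returned mask are modified, so the tight bounding
    box of the mask covers every rendered lesion pixel exactly.
    """
    h, w = canvas.shape[:2]
    m = min(h, w)
    color = np.array(_LESION_COLORS[style])
    margin = int(0.28 * m)
    cy = float(rng.uniform(margin, h - margin))
    cx = float(rng.uniform(margin, w - margin))

    if style == "round-sharp-border":
        r = m * rng.uniform(0.10, 0.16)
        mask = _ellipse_mask(h, w, cy, cx, r, r * rng.uniform(0.85, 1.0))
        rim = mask & ~_ellipse_mask(h, w, cy, cx, 0.75 * r, 0.75 * r)
        canvas[mask] = color
        canvas[rim] = color * 0.55
    elif style == "elongated-streak":
        theta = rng.uniform(0, np.pi)
        rx = m * rng.uniform(0.20, 0.26)
        ry = m * rng.uniform(0.025, 0.045)
        mask = _ellipse_mask(h, w, cy, cx, ry, rx, theta)
        canvas[mask] = color
    elif style in ("white-patch", "yellow-to-gray-patch"):
        # irregular blob: union of jittered ellipses, with noise texture
        mask = np.zeros((h, w), dtype=bool)
        r0 = m * rng.uniform(0.09, 0.13)
        for _ in range(3):
            jy, jx = rng.normal(0, 0.35 * r0, size=2)
            mask |= _ellipse_mask(h, w, cy + jy, cx + jx,
                                  r0 * rng.uniform(0.7, 1.0),
                                  r0 * rng.uniform(0.7, 1.0))
        tex = rng.normal(0, 9.0, size=(h, w, 1))
        canvas[mask] = np.clip(color + tex[mask], 0, 255)
    elif style == "wet-blurred-halo":
        r = m * rng.uniform(0.10, 0.15)
        yy, xx = _grid(h, w)
        d2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / (r * r)
        alpha = np.exp(-1.2 * d2)
        alpha[alpha <= 0.25] = 0.0  # hard cut: nothing rendered outside the mask
        mask = alpha > 0.0
        a = alpha[..., None]
        canvas[:] = (1 - a) * canvas + a * color
    elif style == AMBIGUOUS_STYLE:
        r = m * rng.uniform(0.10, 0.15)
        mask = _ellipse_mask(h, w, cy, cx, r, r)
        inner = _ellipse_mask(h, w, cy, cx, 0.6 * r, 0.6 * r)
        canvas[mask] = color * 0.85
        canvas[inner] = color
    else:  # pragma: no cover
        raise ValueError(f"unknown lesion style {style!r}")
    return mask


def _leaf_background(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    base = np.array([45.0, 112.0, 48.0])
    canvas = base + rng.normal(0, 6.0, size=(h, w, 3))
    # central vein, slightly lighter
    xc = w // 2
    canvas[:, max(xc - 1, 0):xc + 1, :] += 18.0
    return canvas


def _mask_bbox(mask: np.ndarray) -> Tuple[int, int, int, int]:
    ys, xs = np.nonzero(mask)
    return int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1


# ----------------------------------------------------------------- generator

def _draw_window(profile_key: str, window_hours: int,
                 rng: np.random.Generator) -> SensorWindow:
    prof = SENSOR_PROFILES[profile_key]
    rows = []
    for ch in CHANNELS:
        mu, sd = prof[ch]
        rows.append(rng.normal(mu, sd, size=window_hours))
    readings = np.stack(rows)
    hum = CHANNELS.index("humidity")
    readings[hum] = np.clip(readings[hum], 0.0, 100.0)
    return SensorWindow(readings=readings, channel_names=CHANNELS,
                        window_hours=window_hours)


def generate_sample(class_id: int, image_size: Tuple[int, int],
                    window_hours: int, confusability: float,
                    rng: np.random.Generator, image_id: str,
                    multi_lesion: bool = False) -> MultimodalSample:
    h, w = image_size
    cls = DISEASE_CLASSES[class_id]

    image_ambiguous = (class_id in IMAGE_AMBIGUOUS_CLASSES
                       and rng.random() < confusability)
    sensor_ambiguous = (class_id in SENSOR_AMBIGUOUS_CLASSES
                        and rng.random() < confusability)
    style = AMBIGUOUS_STYLE if image_ambiguous else cls.lesion_style
    profile_key = AMBIGUOUS_PROFILE if sensor_ambiguous else cls.name

    canvas = _leaf_background(h, w, rng)
    n_lesions = int(rng.integers(1, 4)) if multi_lesion else 1
    boxes = []
    for _ in range(n_lesions):
        mask = _render_lesion(canvas, style, rng)
        boxes.append(_mask_bbox(mask))
    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)

    image = LabeledImage(pixels=pixels, class_id=class_id, boxes=boxes,
                         image_id=image_id)
    sensors = _draw_window(profile_key, window_hours, rng)
    meta = {"lesion_style": style, "sensor_profile": profile_key,
            "image_ambiguous": bool(image_ambiguous),
            "sensor_ambiguous": bool(sensor_ambiguous)}
    return MultimodalSample(image=image, sensors=sensors, class_id=class_id,
                            meta=meta)


def generate_dataset(n_per_class: int,
                     image_size: Tuple[int, int] = (64, 64),
                     window_hours: int = 24,
                     confusability: float = 0.0,
                     seed: int = 0,
                     multi_lesion: bool = False
                     ) -> Tuple[List[MultimodalSample], Dict]:
    """Generate 5 * n_per_class samples (balanced, deterministic in `seed`)."""
    if n_per_class < 1:
        raise ValueError(f"n_per_class must be >= 1, got {n_per_class}")
    h, w = image_size
    if h < 64 or w < 64:
        raise ValueError(f"image_size must be at least 64x64, got {image_size}")
    if window_hours < 1:
        raise ValueError(f"window_hours must be >= 1, got {window_hours}")
    if not (0.0 <= confusability <= 1.0):
        raise ValueError(f"confusability must be in [0, 1], got {confusability}")

    root = np.random.SeedSequence(seed)
    children = root.spawn(5 * n_per_class)
    samples: List[MultimodalSample] = []
    idx = 0
    for class_id in range(5):
        for k in range(n_per_class):
            rng = np.random.default_rng(children[idx])
            image_id = f"{CLASS_NAMES[class_id]}_{k:05d}"
            samples.append(generate_sample(class_id, image_size, window_hours,
                                           confusability, rng, image_id,
                                           multi_lesion))
            idx += 1
    manifest = {
        "n_per_class": n_per_class,
        "image_size": list(image_size),
        "window_hours": window_hours,
        "confusability": confusability,
        "seed": seed,
        "classes": [{"id": c.id, "name": c.name, "lesion_style": c.lesion_style}
                    for c in DISEASE_CLASSES],
        "samples": [{"image_id": s.image.image_id, "class_id": s.class_id,
                     **s.meta} for s in samples],
    }
    return samples, manifest


# --------------------------------------------------------------- Bayes rules

def bayes_image_predict(sample: MultimodalSample) -> int:
    """Optimal rule given only the image latent (lesion appearance).

    The shared ambiguous appearance carries equal posterior for both classes
    in the pair; the rule deterministically picks the lower class id, which
    is correct half the time — exactly the Bayes rate under a 0/1 loss.
    """
    style = sample.meta["lesion_style"]
    if style == AMBIGUOUS_STYLE:
        return IMAGE_AMBIGUOUS_CLASSES[0]
    return _STYLE_TO_CLASS[style]


def bayes_sensor_predict(sample: MultimodalSample) -> int:
    profile = sample.meta["sensor_profile"]
    if profile == AMBIGUOUS_PROFILE:
        return SENSOR_AMBIGUOUS_CLASSES[0]
    return _PROFILE_TO_CLASS[profile]


def bayes_joint_predict(sample: MultimodalSample) -> int:
    """With both modalities, every planted ambiguity is resolved by the
    other modality (the two plantings affect disjoint class pairs)."""
    if sample.meta["lesion_style"] == AMBIGUOUS_STYLE:
        return bayes_sensor_predict(sample)
    return bayes_image_predict(sample)


def bayes_accuracy(samples: Sequence[MultimodalSample], rule) -> float:
    hits = [rule(s) == s.class_id for s in samples]
    return float(np.mean(hits))


# ------------------------------------------------------------------------ IO

def box_to_coco(box: Tuple[int, int, int, int]) -> List[float]:
    """(x0, y0, x1, y1) half-open -> COCO [x, y, width, height]."""
    x0, y0, x1, y1 = box
    return [float(x0), float(y0), float(x1 - x0), float(y1 - y0)]


def coco_to_box(bbox: Sequence[float]) -> Tuple[int, int, int, int]:
    x, y, bw, bh = bbox
    return int(round(x)), int(round(y)), int(round(x + bw)), int(round(y + bh))


def write_dataset(samples: Sequence[MultimodalSample], out_dir) -> Path:
    """Write PNG images, a COCO-style annotation JSON, and a long-format
    sensor CSV (image_id, timestamp_hour, channel, value). Round-trips
    losslessly through :func:`read_dataset`."""
    if not samples:
        raise ValueError("no samples to write")
    out = Path(out_dir)
    try:
        (out / "images").mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create dataset directory {out}: {e}") from e

    images_json, annotations_json = [], []
    ann_id = 1
    for s in samples:
        img = s.image
        h, w = img.pixels.shape[:2]
        Image.fromarray(img.pixels).save(out / "images" / f"{img.image_id}.png")
        images_json.append({"id": img.image_id,
                            "file_name": f"images/{img.image_id}.png",
                            "width": w, "height": h})
        for b in img.boxes:
            bbox = box_to_coco(b)
            annotations_json.append({"id": ann_id, "image_id": img.image_id,
                                     "category_id": img.class_id, "bbox": bbox,
                                     "area": bbox[2] * bbox[3], "iscrowd": 0})
            ann_id += 1
    coco = {"images": images_json, "annotations": annotations_json,
            "categories": [{"id": c.id, "name": c.name}
                           for c in DISEASE_CLASSES]}
    (out / "annotations.json").write_text(json.dumps(coco, indent=1))

    rows = []
    for s in samples:
        for ci, ch in enumerate(s.sensors.channel_names):
            for t in range(s.sensors.window_hours):
                rows.append((s.image.image_id, t, ch,
                             float(s.sensors.readings[ci, t])))
    df = pd.DataFrame(rows, columns=["image_id", "timestamp_hour", "channel",
                                     "value"])
    df.to_csv(out / "sensors.csv", index=False, float_format="%.17g")

    latents = {s.image.image_id: {"class_id": s.class_id, **s.meta}
               for s in samples}
    (out / "latents.json").write_text(json.dumps(latents, indent=1))
    return out


def read_dataset(dir_path) -> List[MultimodalSample]:
    """Load and validate a dataset written by :func:`write_dataset` (or
    conforming external data; `latents.json` is optional)."""
    root = Path(dir_path)
    ann_path = root / "annotations.json"
    csv_path = root / "sensors.csv"
    if not ann_path.exists():
        raise FileNotFoundError(f"missing annotation file {ann_path}")
    if not csv_path.exists():
        raise FileNotFoundError(f"missing sensor file {csv_path}")
    coco = json.loads(ann_path.read_text())
    latents = {}
    if (root / "latents.json").exists():
        latents = json.loads((root / "latents.json").read_text())

    images_by_id = {im["id"]: im for im in coco["images"]}
    anns_by_image: Dict[str, list] = {i: [] for i in images_by_id}
    for a in coco["annotations"]:
        if a["image_id"] not in images_by_id:
            raise DatasetValidationError(
                f"annotation {a['id']} references missing image_id "
                f"{a['image_id']!r}")
        anns_by_image[a["image_id"]].append(a)

    df = pd.read_csv(csv_path, float_precision="round_trip")
    expected_cols = ["image_id", "timestamp_hour", "channel", "value"]
    if list(df.columns) != expected_cols:
        raise DatasetValidationError(
            f"sensor CSV columns {list(df.columns)} != {expected_cols}")
    sensor_groups = dict(tuple(df.groupby("image_id", sort=False)))

    samples = []
    for image_id, im in images_by_id.items():
        png = root / im["file_name"]
        if not png.exists():
            raise FileNotFoundError(f"missing image file {png}")
        pixels = np.asarray(Image.open(png).convert("RGB"))
        anns = anns_by_image[image_id]
        if not anns:
            raise DatasetValidationError(f"{image_id}: no annotations")
        class_ids = {a["category_id"] for a in anns}
        if len(class_ids) != 1:
            raise DatasetValidationError(
                f"{image_id}: conflicting category ids {sorted(class_ids)}")
        class_id = class_ids.pop()
        boxes = [coco_to_box(a["bbox"]) for a in anns]

        if image_id not in sensor_groups:
            raise DatasetValidationError(f"{image_id}: no sensor readings")
        g = sensor_groups[image_id]
        hours = sorted(g["timestamp_hour"].unique())
        t = len(hours)
        if hours != list(range(t)):
            raise DatasetValidationError(
                f"{image_id}: sensor hours not contiguous from 0")
        readings = np.empty((len(CHANNELS), t))
        for ci, ch in enumerate(CHANNELS):
            sub = g[g["channel"] == ch].sort_values("timestamp_hour")
            if len(sub) != t:
                raise DatasetValidationError(
                    f"{image_id}: channel {ch!r} has {len(sub)} readings, "
                    f"expected {t}")
            readings[ci] = sub["value"].to_numpy()

        image = LabeledImage(pixels=pixels, class_id=class_id, boxes=boxes,
                             image_id=image_id)
        window = SensorWindow(readings=readings, channel_names=CHANNELS,
                              window_hours=t)
        meta = dict(latents.get(image_id, {}))
        meta.pop("class_id", None)
        sample = MultimodalSample(image=image, sensors=window,
                                  class_id=class_id, meta=meta)
        sample.validate()
        samples.append(sample)
    return samples
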