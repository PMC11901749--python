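"""Lesion-aware image augmentation: CutMix, Mosaic, GridMask.

CutMix supports two modes: "region" (a rectangle of image B replaces the
corresponding rectangle of image A; the mixing ratio is the *realized*
retained-area fraction) and "blend" (the literal pixel-wise convex
combination X = lam*XA + (1-lam)*XB).  With lesion preservation enabled the
pasted rectangle is re-sampled so it neither covers a lesion of A nor
truncates a lesion of B, and GridMask forces its mask to 1 inside every
lesion box.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .syndata import LabeledImage

logger = logging.getLogger(__name__)

N_CLASSES = 5
Box = Tuple[int, int, int, int]


def one_hot(class_id: int, n_classes: int = N_CLASSES) -> np.ndarray:
    y = np.zeros(n_classes)
    y[class_id] = 1.0
    return y


@dataclass
class MixResult:
    pixels: np.ndarray
    label: np.ndarray              # length-5 probability vector
    boxes: List[Box]
    lam: float
    source_ids: Tuple[str, ...]

    def __post_init__(self):
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError(f"lam {self.lam} outside [0, 1]")
        if (self.label < 0).any() or abs(self.label.sum() - 1.0) > 1e-9:
            raise ValueError("label must be a probability vector")


@dataclass
class GridMaskSpec:
    unit: int                      # grid period in pixels
    ratio: float                   # kept fraction per cell, in (0, 1)
    offset: Tuple[int, int]        # (dx, dy) phase
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.unit < 2:
            raise ValueError(f"unit must be >= 2, got {self.unit}")
        if not (0.0 < self.ratio < 1.0):
            raise ValueError(f"ratio must be in (0, 1), got {self.ratio}")

    @property
    def drop_side(self) -> int:
        """Side of the square dropped in each cell."""
        return int(round(self.unit * np.sqrt(1.0 - self.ratio)))

    @property
    def kept_fraction(self) -> float:
        """Analytic kept fraction implied by (unit, ratio) after rounding."""
        return 1.0 - (self.drop_side / self.unit) ** 2


def _boxes_disjoint(rect: Box, boxes: Sequence[Box]) -> bool:
    rx0, ry0, rx1, ry1 = rect
    for (x0, y0, x1, y1) in boxes:
        if not (x1 <= rx0 or rx1 <= x0 or y1 <= ry0 or ry1 <= y0):
            return False
    return True


def _box_inside(inner: Box, outer: Box) -> bool:
    return (outer[0] <= inner[0] and outer[1] <= inner[1]
            and inner[2] <= outer[2] and inner[3] <= outer[3])


def cutmix(a: LabeledImage, b: LabeledImage, beta_alpha: float = 1.0,
           mode: str = "region", preserve_lesions: bool = True,
           seed: int = 0, max_attempts: int = 100) -> MixResult:
    """Mix two images and their labels.

    region mode: lam = fraction of pixels retained from `a`; label =
    lam*y_a + (1-lam)*y_b.  blend mode: pixel-wise convex combination with
    lam ~ Beta(beta_alpha, beta_alpha).
    """
    if a.pixels.shape != b.pixels.shape:
        raise ValueError(f"size mismatch: {a.pixels.shape} vs {b.pixels.shape}")
    if mode not in ("region", "blend"):
        raise ValueError(f"unknown cutmix mode {mode!r}")
    rng = np.random.default_rng(seed)
    h, w = a.pixels.shape[:2]
    y_a, y_b = one_hot(a.class_id), one_hot(b.class_id)
    ids = (a.image_id, b.image_id)

    if mode == "blend":
        lam = float(rng.beta(beta_alpha, beta_alpha))
        px = lam * a.pixels.astype(np.float64) + (1 - lam) * b.pixels
        return MixResult(pixels=np.clip(np.rint(px), 0, 255).astype(np.uint8),
                         label=lam * y_a + (1 - lam) * y_b,
                         boxes=list(a.boxes) + list(b.boxes),
                         lam=lam, source_ids=ids)

    lam_target = float(rng.beta(beta_alpha, beta_alpha))
    cut = np.sqrt(max(0.0, 1.0 - lam_target))
    rw, rh = int(round(w * cut)), int(round(h * cut))

    rect = None
    for _ in range(max_attempts):
        if rw == 0 or rh == 0:
            rect = (0, 0, 0, 0)
            break
        x0 = int(rng.integers(0, w - rw + 1))
        y0 = int(rng.integers(0, h - rh + 1))
        cand = (x0, y0, x0 + rw, y0 + rh)
        if not preserve_lesions:
            rect = cand
            break
        # must not cover any lesion of a, nor truncate any lesion of b
        if not _boxes_disjoint(cand, a.boxes):
            continue
        if all(_box_inside(bb, cand) or _boxes_disjoint(cand, [bb])
               for bb in b.boxes):
            rect = cand
            break
    if rect is None:
        logger.warning("cutmix: no admissible paste region after %d attempts; "
                       "falling back to identity mix (lam=1)", max_attempts)
        return MixResult(pixels=a.pixels.copy(), label=y_a.copy(),
                         boxes=list(a.boxes), lam=1.0, source_ids=ids)

    x0, y0, x1, y1 = rect
    pixels = a.pixels.copy()
    pixels[y0:y1, x0:x1] = b.pixels[y0:y1, x0:x1]
    area = (x1 - x0) * (y1 - y0)
    lam = 1.0 - area / (h * w)
    boxes = list(a.boxes) + [bb for bb in b.boxes if _box_inside(bb, rect)]
    return MixResult(pixels=pixels, label=lam * y_a + (1 - lam) * y_b,
                     boxes=boxes, lam=lam, source_ids=ids)


def _resize_nearest(pixels: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    h, w = pixels.shape[:2]
    ys = np.minimum((np.arange(out_h) + 0.5) * h / out_h, h - 1).astype(int)
    xs = np.minimum((np.arange(out_w) + 0.5) * w / out_w, w - 1).astype(int)
    return pixels[np.ix_(ys, xs)]


def mosaic(imgs: Sequence[LabeledImage], canvas: Tuple[int, int],
           split: Union[str, Tuple[int, int]] = "random", seed: int = 0,
           min_box_frac: float = 0.2) -> MixResult:
    """Tile four images onto one canvas: 1 top-left, 2 top-right, 3
    bottom-left, 4 bottom-right, split at (h1, w1).  Boxes are scaled and
    translated into their quadrant and clipped; a box whose clipped area
    falls below `min_box_frac` of its scaled area is dropped.  The composite
    label is the quadrant-area-weighted mixture of the four one-hot labels.
    """
    if len(imgs) != 4:
        raise ValueError(f"mosaic needs exactly 4 images, got {len(imgs)}")
    ch, cw = canvas
    rng = np.random.default_rng(seed)
    if split == "random":
        h1 = int(rng.integers(ch // 4, 3 * ch // 4 + 1))
        w1 = int(rng.integers(cw // 4, 3 * cw // 4 + 1))
    else:
        h1, w1 = split
    if not (0 < h1 < ch and 0 < w1 < cw):
        raise ValueError(f"degenerate split ({h1}, {w1}) for canvas {canvas}")

    quads = [  # (y0, x0, qh, qw) in placement order
        (0, 0, h1, w1), (0, w1, h1, cw - w1),
        (h1, 0, ch - h1, w1), (h1, w1, ch - h1, cw - w1),
    ]
    out = np.zeros((ch, cw, 3), dtype=imgs[0].pixels.dtype)
    label = np.zeros(N_CLASSES)
    boxes: List[Box] = []
    for img, (qy, qx, qh, qw) in zip(imgs, quads):
        out[qy:qy + qh, qx:qx + qw] = _resize_nearest(img.pixels, qh, qw)
        label += (qh * qw) / (ch * cw) * one_hot(img.class_id)
        sh, sw = img.pixels.shape[:2]
        sy, sx = qh / sh, qw / sw
        for (x0, y0, x1, y1) in img.boxes:
            nx0, ny0 = qx + x0 * sx, qy + y0 * sy
            nx1, ny1 = qx + x1 * sx, qy + y1 * sy
            scaled_area = (nx1 - nx0) * (ny1 - ny0)
            cx0, cy0 = max(nx0, qx), max(ny0, qy)
            cx1, cy1 = min(nx1, qx + qw), min(ny1, qy + qh)
            clipped = max(0.0, cx1 - cx0) * max(0.0, cy1 - cy0)
            if scaled_area > 0 and clipped / scaled_area >= min_box_frac:
                bx = (int(np.floor(cx0)), int(np.floor(cy0)),
                      int(np.ceil(cx1)), int(np.ceil(cy1)))
                if bx[0] < bx[2] and bx[1] < bx[3]:
                    boxes.append(bx)
    # lam reported as the first (top-left) quadrant's area weight
    return MixResult(pixels=out, label=label, boxes=boxes,
                     lam=float(h1 * w1 / (ch * cw)),
                     source_ids=tuple(i.image_id for i in imgs))


def build_grid_mask(h: int, w: int, spec: GridMaskSpec) -> np.ndarray:
    """Binary mask: 1 = keep.  In every unit x unit cell a `drop_side`-sided
    square (anchored at the cell origin plus the phase offset) is zeroed."""
    d = spec.drop_side
    mask = np.ones((h, w), dtype=np.uint8)
    if d == 0:
        return mask
    dx, dy = spec.offset
    u = spec.unit
    ys = np.arange(h)
    xs = np.arange(w)
    in_y = ((ys - dy) % u) < d
    in_x = ((xs - dx) % u) < d
    mask[np.ix_(in_y, in_x)] = 0
    return mask


def gridmask(img: LabeledImage, spec: Union[GridMaskSpec, str] = "random",
             preserve_lesions: bool = True, seed: int = 0) -> LabeledImage:
    """X' = X (element-wise) M, M a periodic binary grid mask.  Lesion boxes
    are exempted (mask forced to 1 inside them) when preservation is on.
    Label and boxes are unchanged."""
    h, w = img.pixels.shape[:2]
    rng = np.random.default_rng(seed)
    if spec == "random":
        m = min(h, w)
        unit = int(rng.integers(max(2, m // 8), max(3, m // 4 + 1)))
        ratio = float(rng.uniform(0.3, 0.6))
        offset = (int(rng.integers(0, unit)), int(rng.integers(0, unit)))
        spec = GridMaskSpec(unit=unit, ratio=ratio, offset=offset)
    mask = spec.mask if spec.mask is not None else build_grid_mask(h, w, spec)
    mask = mask.astype(np.uint8).copy()
    if preserve_lesions:
        for (x0, y0, x1, y1) in img.boxes:
            mask[y0:y1, x0:x1] = 1
    out = img.pixels * mask[..., None]
    return LabeledImage(pixels=out.astype(img.pixels.dtype),
                        class_id=img.class_id, boxes=list(img.boxes),
                        image_id=f"{img.image_id}+gridmask")
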