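"""End-to-end training and evaluation harness.

Model assembly: modality encoders -> token projections -> attention ->
fusion -> ReLU projection head -> class logits + a single-box regressor
(normalized coordinates, smooth-L1).  The box head is a deliberately
minimal mechanism so that IoU-matched mAP@75 is exercisable end to end; it
is an artifact of this framework, not a full detector.

Optimization: Adam, cosine-annealed learning rate, L2 weight decay, seeded
substreams for data splitting, initialization, shuffling and augmentation.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .attend import CBAM, EmbeddingAttentionStack
from .augment import cutmix, gridmask, mosaic, one_hot
from .config import RunConfig
from .encode import SensorEncoder, TinyCNN
from .fuse import FusionModule, fuse
from .loss import (LossConfig, alignment_loss, cross_entropy, focal_loss,
                   inverse_frequency_weights)
from .metrics import Detection, EvalReport, classification_metrics, map_at
from .nn import Adam, Linear, Module, Tensor, clip_min, concatenate, cosine_lr, softmax
from .syndata import MultimodalSample

logger = logging.getLogger(__name__)

N_CLASSES = 5

CHECKPOINT_VERSION = 1


# ------------------------------------------------------------------- splits

def split_cv(labels: Sequence[int], mode: str = "holdout_70_15_15",
             seed: int = 0):
    """Stratified data splits.

    holdout_70_15_15 -> {"train": idx, "val": idx, "test": idx} with each
    class within one sample of its proportional share; cv5 -> list of five
    disjoint covering folds, stratified the same way.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC5)))
    if mode == "holdout_70_15_15":
        parts = {"train": [], "val": [], "test": []}
        for c in np.unique(labels):
            idx = np.flatnonzero(labels == c)
            rng.shuffle(idx)
            n = len(idx)
            n_tr = int(round(0.70 * n))
            n_val = int(round(0.15 * n))
            parts["train"].extend(idx[:n_tr])
            parts["val"].extend(idx[n_tr:n_tr + n_val])
            parts["test"].extend(idx[n_tr + n_val:])
        return {k: np.sort(np.array(v, dtype=int)) for k, v in parts.items()}
    if mode == "cv5":
        folds = [[] for _ in range(5)]
        for c in np.unique(labels):
            idx = np.flatnonzero(labels == c)
            rng.shuffle(idx)
            for i, j in enumerate(idx):
                folds[i % 5].append(j)
        return [np.sort(np.array(f, dtype=int)) for f in folds]
    raise ValueError(f"unknown split mode {mode!r}")


# -------------------------------------------------------------------- model

class MultimodalNet(Module):
    """Encoders -> attention -> fusion -> head, per the run configuration."""

    def __init__(self, cfg: RunConfig, seed: int = 0):
        ss = np.random.SeedSequence((seed, 0x11))
        seeds = ss.generate_state(8)
        rng = np.random.default_rng(seeds[0])
        d = cfg.fusion.dim
        self.cfg = cfg
        self.modality = cfg.modality
        self.att_kind = cfg.attention.kind

        if cfg.modality in ("image", "both"):
            if cfg.encoder.image.backbone != "tinycnn":
                raise NotImplementedError(
                    "only the tinycnn backbone is trainable in this build")
            self.cnn = TinyCNN(cfg.encoder.image.channels, seed=int(seeds[1]))
            self.img_proj = Linear(cfg.encoder.image.channels, d, rng)
            if cfg.attention.kind == "cbam":
                self.cbam = CBAM(cfg.encoder.image.channels, seed=int(seeds[2]))
        if cfg.modality in ("sensor", "both"):
            self.sensor_enc = SensorEncoder(bins=cfg.encoder.sensor.bins,
                                            layers=cfg.encoder.sensor.layers,
                                            dim=cfg.encoder.sensor.dim,
                                            seed=int(seeds[3]))
            self.sens_proj = Linear(cfg.encoder.sensor.dim, d, rng)
        if cfg.attention.kind in ("self", "embedding"):
            self.att = EmbeddingAttentionStack(d, cfg.attention.layers,
                                               seed=int(seeds[4]))
        if cfg.modality == "both":
            self.fusion = FusionModule(d, mode=cfg.fusion.mode,
                                       alpha_init=cfg.fusion.alpha_init,
                                       seed=int(seeds[5]))
            fm_dim = self.fusion.out_dim
        else:
            fm_dim = d
        self.head_fc = Linear(fm_dim, cfg.head_dim, rng)   # Fm' = ReLU(Wf Fm + bf)
        self.cls = Linear(cfg.head_dim, N_CLASSES, rng)
        self.box = Linear(cfg.head_dim, 4, rng)

    def forward(self, images: Optional[np.ndarray],
                sensors: Optional[np.ndarray]) -> Dict[str, Tensor]:
        """images: (B, H, W, 3) float in [0,1]; sensors: (B, C, T)."""
        tokens_v = tokens_t = None
        if self.modality in ("image", "both"):
            x = Tensor(np.ascontiguousarray(images.transpose(0, 3, 1, 2)))
            fmap = self.cnn(x)                              # (B, Cv, hv, wv)
            if self.att_kind == "cbam":
                fmap = self.cbam(fmap)
            b, cv, hv, wv = fmap.shape
            tokens_v = self.img_proj(
                fmap.reshape(b, cv, hv * wv).swapaxes(1, 2))  # (B, Nv, D)
        if self.modality in ("sensor", "both"):
            tokens_t = self.sens_proj(self.sensor_enc(sensors))  # (B, Nt, D)

        if self.att_kind == "embedding":
            if tokens_v is not None and tokens_t is not None:
                nv = tokens_v.shape[1]
                joint = self.att(concatenate([tokens_v, tokens_t], axis=1))
                tokens_v = joint[:, :nv]
                tokens_t = joint[:, nv:]
            elif tokens_v is not None:
                tokens_v = self.att(tokens_v)
            else:
                tokens_t = self.att(tokens_t)
        elif self.att_kind == "self" and tokens_v is not None:
            tokens_v = self.att(tokens_v)

        fv = tokens_v.mean(axis=1) if tokens_v is not None else None
        ft = tokens_t.mean(axis=1) if tokens_t is not None else None
        if self.modality == "both":
            if self.cfg.fusion.mode == "bilinear":
                fm = self.fusion(tokens_v, ft)
            else:
                fm = self.fusion(fv, ft)
        else:
            fm = fv if fv is not None else ft
        fm_prime = self.head_fc(fm).relu()
        logits = self.cls(fm_prime)
        box = self.box(fm_prime).sigmoid()
        out = {"logits": logits, "probs": softmax(logits, axis=-1),
               "box": box, "fm_prime": fm_prime}
        if fv is not None:
            out["fv"] = fv
        if ft is not None:
            out["ft"] = ft
        return out


@dataclass
class TrainedModel:
    net: MultimodalNet
    cfg: RunConfig
    log: List[dict] = field(default_factory=list)
    splits: Optional[dict] = None
    class_weights: Optional[np.ndarray] = None


# --------------------------------------------------------------- data prep

def _images_array(samples: Sequence[MultimodalSample]) -> np.ndarray:
    return np.stack([s.image.pixels for s in samples]).astype(np.float64) / 255.0


def _sensors_array(samples: Sequence[MultimodalSample]) -> np.ndarray:
    return np.stack([s.sensors.readings for s in samples])


def _norm_box(box, h, w) -> np.ndarray:
    x0, y0, x1, y1 = box
    return np.array([x0 / w, y0 / h, x1 / w, y1 / h])


def _smooth_l1(pred: Tensor, target: np.ndarray, mask: np.ndarray) -> Tensor:
    """Masked smooth-L1 (Huber, delta=1) averaged over supervised samples."""
    d = pred - Tensor(target)
    absd = d.relu() + (-d).relu()
    quad = Tensor((absd.data < 1.0).astype(float))
    per = quad * (0.5 * d * d) + (1.0 - quad) * (absd - 0.5)
    per = per.sum(axis=-1) * Tensor(mask)
    denom = max(float(mask.sum()), 1.0)
    return per.sum() * (1.0 / denom)


def _augment_batch(batch: List[MultimodalSample], pool: List[MultimodalSample],
                   ops: Sequence[str], prob: float,
                   rng: np.random.Generator
                   ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Apply per-sample augmentation; returns (images, labels, boxes, box_mask).
    Sensor windows pass through unchanged (augmentation is image-side only)."""
    h, w = batch[0].image.pixels.shape[:2]
    imgs, labels, boxes, mask = [], [], [], []
    for s in batch:
        img, label, bxs = s.image, one_hot(s.class_id), list(s.image.boxes)
        if ops and rng.random() < prob:
            op = ops[int(rng.integers(0, len(ops)))]
            seed = int(rng.integers(0, 2 ** 31))
            if op == "cutmix":
                partner = pool[int(rng.integers(0, len(pool)))]
                res = cutmix(img, partner.image, seed=seed)
                px, label, bxs = res.pixels, res.label, res.boxes
            elif op == "mosaic":
                partners = [pool[int(rng.integers(0, len(pool)))].image
                            for _ in range(3)]
                res = mosaic([img] + partners, canvas=(h, w), seed=seed)
                px, label, bxs = res.pixels, res.label, res.boxes
            else:  # gridmask
                aug = gridmask(img, seed=seed)
                px, bxs = aug.pixels, list(aug.boxes)
            imgs.append(px)
        else:
            imgs.append(img.pixels)
        labels.append(label)
        if bxs:
            boxes.append(_norm_box(bxs[0], h, w))
            mask.append(1.0)
        else:
            boxes.append(np.zeros(4))
            mask.append(0.0)
    return (np.stack(imgs).astype(np.float64) / 255.0, np.stack(labels),
            np.stack(boxes), np.array(mask))


# ----------------------------------------------------------------- training

def train_model(samples: Sequence[MultimodalSample], cfg: RunConfig,
                splits: Optional[dict] = None) -> TrainedModel:
    """Train a model per `cfg`; deterministic given cfg.seed."""
    for s in samples:
        s.validate()
    labels = [s.class_id for s in samples]
    if splits is None:
        sp = split_cv(labels, cfg.split, seed=cfg.seed)
        if cfg.split == "cv5":
            # fold 0 tests, fold 1 validates, remaining folds train
            splits = {"test": sp[0], "val": sp[1],
                      "train": np.sort(np.concatenate(sp[2:]))}
        else:
            splits = sp

    train_s = [samples[i] for i in splits["train"]]
    val_s = [samples[i] for i in splits["val"]]

    net = MultimodalNet(cfg, seed=cfg.seed)
    if cfg.modality in ("sensor", "both"):
        net.sensor_enc.fit_standardizer([s.sensors for s in train_s])

    class_weights = None
    if cfg.loss.class_weights == "inverse_frequency":
        y_train = np.stack([one_hot(s.class_id) for s in train_s])
        class_weights = inverse_frequency_weights(y_train)
    elif isinstance(cfg.loss.class_weights, list):
        class_weights = np.asarray(cfg.loss.class_weights, dtype=float)

    opt = Adam(list(net.parameters()), lr=cfg.lr,
               weight_decay=cfg.weight_decay)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0x5F)))
    aug_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0xA6)))

    model = TrainedModel(net=net, cfg=cfg, splits=splits,
                         class_weights=class_weights)
    n_train = len(train_s)
    for epoch in range(cfg.epochs):
        lr = cosine_lr(cfg.lr, epoch, cfg.epochs) \
            if cfg.schedule == "cosine" else cfg.lr
        opt.lr = lr
        order = shuffle_rng.permutation(n_train)
        ep_loss, ep_ce, ep_align, n_batches = 0.0, 0.0, 0.0, 0
        for lo in range(0, n_train, cfg.batch_size):
            batch = [train_s[i] for i in order[lo:lo + cfg.batch_size]]
            use_aug = cfg.augmentation if cfg.modality != "sensor" else []
            imgs, y, bx, bmask = _augment_batch(batch, train_s, use_aug,
                                                cfg.augment_prob, aug_rng)
            sens = _sensors_array(batch) if cfg.modality != "image" else None
            out = net(imgs if cfg.modality != "sensor" else None, sens)
            probs = clip_min(out["probs"], 1e-12)

            if cfg.loss.kind == "focal":
                cls_loss = focal_loss(probs, y, gamma=cfg.loss.focal_gamma,
                                      alpha=cfg.loss.focal_alpha,
                                      weights=class_weights)
            else:
                cls_loss = cross_entropy(probs, y, weights=class_weights)
            total = cls_loss
            align_val = 0.0
            if (cfg.loss.kind == "embedding" and cfg.modality == "both"
                    and cfg.loss.lambda_align > 0):
                al = alignment_loss(out["fv"], out["ft"])
                total = total + cfg.loss.lambda_align * al
                align_val = float(al.data)
            if cfg.lambda_box > 0:
                total = total + cfg.lambda_box * _smooth_l1(out["box"], bx, bmask)

            if not np.isfinite(total.data):
                raise RuntimeError(
                    f"NaN/Inf loss at epoch {epoch}, batch {n_batches}; "
                    f"sample ids: {[s.image.image_id for s in batch]}")
            net.zero_grad()
            total.backward()
            opt.step()
            ep_loss += float(total.data)
            ep_ce += float(cls_loss.data)
            ep_align += align_val
            n_batches += 1

        val_report = evaluate_model(model, val_s, detections=False)
        model.log.append({
            "epoch": epoch, "lr": lr,
            "loss": ep_loss / n_batches, "ce": ep_ce / n_batches,
            "align": ep_align / n_batches,
            "val_accuracy": val_report.macro["accuracy"],
        })
        logger.info("epoch %d: loss=%.4f val_acc=%.3f lr=%.5f", epoch,
                    ep_loss / n_batches, val_report.macro["accuracy"], lr)
    return model


def predict(model: TrainedModel, samples: Sequence[MultimodalSample],
            batch_size: int = 64) -> Dict[str, np.ndarray]:
    cfg = model.cfg
    if not samples:
        return {"probs": np.zeros((0, N_CLASSES)), "boxes": np.zeros((0, 4))}
    probs, boxes = [], []
    for lo in range(0, len(samples), batch_size):
        chunk = samples[lo:lo + batch_size]
        imgs = _images_array(chunk) if cfg.modality != "sensor" else None
        sens = _sensors_array(chunk) if cfg.modality != "image" else None
        out = model.net(imgs, sens)
        probs.append(out["probs"].data)
        boxes.append(out["box"].data)
    return {"probs": np.concatenate(probs), "boxes": np.concatenate(boxes)}


def evaluate_model(model: TrainedModel, samples: Sequence[MultimodalSample],
                   iou_thresh: float = 0.75,
                   detections: bool = True) -> EvalReport:
    """Confusion-matrix classification metrics plus (optionally) IoU-matched
    mAP from the single-box head (score = max class probability)."""
    out = predict(model, samples)
    preds = out["probs"].argmax(axis=1)
    cm = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    for s, p in zip(samples, preds):
        cm[s.class_id, p] += 1
    per_class, macro = classification_metrics(cm)
    report = EvalReport(per_class=per_class, macro=macro, confusion=cm)
    if detections:
        dets = []
        gts: Dict[str, Dict[int, list]] = {}
        for s, p, bx, pr in zip(samples, preds, out["boxes"], out["probs"]):
            h, w = s.image.pixels.shape[:2]
            x0, y0, x1, y1 = bx[0] * w, bx[1] * h, bx[2] * w, bx[3] * h
            if x1 <= x0:
                x1 = x0 + 1e-3
            if y1 <= y0:
                y1 = y0 + 1e-3
            dets.append(Detection(image_id=s.image.image_id, class_id=int(p),
                                  box=(x0, y0, x1, y1),
                                  score=float(pr.max())))
            gts[s.image.image_id] = {s.class_id: list(s.image.boxes)}
        map75, per_ap = map_at(dets, gts, iou_thresh=iou_thresh)
        report.macro["map75"] = map75
        for c, ap in per_ap.items():
            report.per_class[c]["ap75"] = ap
    return report


# ----------------------------------------------------------------- ablation

_AXIS_SETTERS = {
    "modality": lambda cfg, v: cfg.__setattr__("modality", v),
    "attention": lambda cfg, v: cfg.attention.__setattr__("kind", v),
    "loss": lambda cfg, v: cfg.loss.__setattr__("kind", v),
    "augmentation": lambda cfg, v: cfg.__setattr__("augmentation", list(v)),
}


def run_ablation(grid: Dict[str, Sequence], base_cfg: RunConfig,
                 samples: Sequence[MultimodalSample], seeds: Sequence[int],
                 out_csv: Optional[str] = None) -> pd.DataFrame:
    """Train/evaluate every cell of `grid` x `seeds`; one row per run plus
    mean/sd aggregation columns.  A failed cell is recorded, not fatal."""
    unknown = set(grid) - set(_AXIS_SETTERS)
    if unknown:
        raise ValueError(f"unknown ablation axes: {sorted(unknown)}")
    axes = sorted(grid)
    rows = []
    for values in itertools.product(*(grid[a] for a in axes)):
        cell = dict(zip(axes, values))
        for seed in seeds:
            cfg = base_cfg.model_copy(deep=True)
            cfg.seed = int(seed)
            for a, v in cell.items():
                _AXIS_SETTERS[a](cfg, v)
            label = {k: (",".join(v) if isinstance(v, (list, tuple)) else v)
                     for k, v in cell.items()}
            try:
                model = train_model(samples, cfg)
                rep = evaluate_model(
                    model, [samples[i] for i in model.splits["test"]])
                rows.append({**label, "seed": seed, "status": "ok",
                             "accuracy": rep.macro["accuracy"],
                             "precision": rep.macro["precision"],
                             "recall": rep.macro["recall"],
                             "map75": rep.macro.get("map75", np.nan)})
            except Exception as e:  # noqa: BLE001 - harness must continue
                logger.error("ablation cell %s seed %d failed: %s", cell, seed, e)
                rows.append({**label, "seed": seed, "status": f"error: {e}",
                             "accuracy": np.nan, "precision": np.nan,
                             "recall": np.nan, "map75": np.nan})
    df = pd.DataFrame(rows)
    if out_csv:
        df.to_csv(out_csv, index=False)
    return df


def summarize_ablation(df: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd per cell across seeds, in a compact comparison table."""
    axes = [c for c in df.columns
            if c in ("modality", "attention", "loss", "augmentation")]
    metrics = ["precision", "recall", "accuracy", "map75"]
    agg = df[df.status == "ok"].groupby(axes)[metrics].agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.reset_index()


# -------------------------------------------------------------- checkpoints

def save_checkpoint(model: TrainedModel, path) -> None:
    """Single-file container: npz with parameters plus a JSON meta entry."""
    meta = {"version": CHECKPOINT_VERSION,
            "config": model.cfg.model_dump(mode="json")}
    arrays = {f"param/{k}": v for k, v in model.net.state_dict().items()}
    if getattr(model.net, "sensor_enc", None) is not None:
        mu, sd = model.net.sensor_enc.standardizer
        if mu is not None:
            arrays["stat/mu"], arrays["stat/sd"] = mu, sd
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> TrainedModel:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"].tobytes()).decode())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        cfg = RunConfig.model_validate(meta["config"])
        net = MultimodalNet(cfg, seed=cfg.seed)
        state = {k[len("param/"):]: z[k] for k in z.files
                 if k.startswith("param/")}
        net.load_state_dict(state)
        if "stat/mu" in z.files and getattr(net, "sensor_enc", None) is not None:
            net.sensor_enc.set_standardizer(z["stat/mu"], z["stat/sd"])
    return TrainedModel(net=net, cfg=cfg)
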