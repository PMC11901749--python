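# phytofuse

A desk-scale, fully tested framework for multimodal plant-disease detection
that fuses leaf **images** with environmental **sensor windows**
(temperature, humidity, light, CO2). It implements:

- **Synthetic multimodal data generation** (`phytofuse.syndata`): 5 disease
  classes with class-specific parametric lesion morphologies and
  class-conditional sensor profiles. A `confusability` knob plants two
  controlled ambiguities — a shared lesion appearance for
  `brown_spot`/`bacterial_leaf_spot` and a shared sensor profile for
  `fusarium_wilt`/`leaf_mold` — so image-only and sensor-only Bayes-optimal
  accuracy are analytically bounded (1 − c/5) while both modalities jointly
  identify every sample. Datasets round-trip to disk as PNG + COCO-style
  JSON + a long-format sensor CSV.
- **Lesion-aware augmentation** (`phytofuse.augment`): CutMix (region and
  pixel-blend modes), Mosaic (four-image tiling with box remapping), and
  GridMask (periodic occlusion), each with a preservation mode that keeps
  lesion boxes untouched.
- **Modality encoders** (`phytofuse.encode`): a small convolutional image
  backbone (`tinycnn`) and a transformer-style encoder over binned,
  standardized sensor tokens.
- **Fusion** (`phytofuse.fuse`): weighted sum / weighted concatenation
  (default) / plain concatenation / bilinear-softmax, plus a histogram-KL
  modality-divergence diagnostic.
- **Attention** (`phytofuse.attend`): *embedding attention* — scaled
  dot-product self-attention applied jointly over both modalities' tokens —
  with ablation baselines: image-only self-attention, channel attention,
  spatial attention, CBAM.
- **Losses** (`phytofuse.loss`): soft-label cross-entropy, focal loss,
  cosine alignment loss, and the composite *embedding loss*
  `CE + lambda * (1 - cos)` with optional inverse-frequency class weights.
- **Metrics** (`phytofuse.metrics`): precision/recall/accuracy from the
  confusion matrix, IoU, per-class average precision (all-point
  interpolation, oracle-verified) and mAP@75.
- **Training harness** (`phytofuse.train`): Adam + cosine annealing,
  stratified 70/15/15 or 5-fold splits, seeded determinism, ablation grids
  over modality/attention/loss/augmentation.
- **Compression** (`phytofuse.compress`): magnitude pruning
  (keep iff |w| > eps) and uniform quantization (round-half-to-even codes)
  with before/after accuracy reporting.

Everything trainable runs on a small numpy reverse-mode autodiff engine
(`phytofuse.nn`) whose gradients are finite-difference verified — no deep
learning framework is required.

## CLI

```bash
phytofuse generate --n-per-class 50 --confusability 0.5 --seed 1 --out data/
phytofuse augment  --op gridmask --in data/ --out data_aug/ --seed 1
phytofuse train    --config run.yaml --data data/ --out runs/exp1/
phytofuse evaluate --pred dets.json --gt data/annotations.json --iou 0.75
phytofuse ablate   --config run.yaml --data data/ --axes modality --seeds 1,2,3 --out runs/ablation/
phytofuse compress --checkpoint runs/exp1/checkpoint.npz --epsilon 0.01 --delta 0.01 --eval data/
```

Every subcommand writes a `run_manifest.json` (config hash, seed
substreams, timestamps, artifact paths). Configs are strict YAML — unknown
keys and wrong types are rejected with the offending key named. An empty
config file yields all defaults (`lr: 0.001`, `weight_decay: 1e-4`,
`batch_size: 32`, cosine schedule, 70/15/15 split).

Example `run.yaml`:

```yaml
modality: both
epochs: 15
attention: {kind: embedding, layers: 2}
loss: {kind: embedding, lambda_align: 0.5}
fusion: {mode: weighted_concat, dim: 32}
encoder:
  sensor: {bins: 6, layers: 2, dim: 32}
augmentation: [cutmix, gridmask]
```

### Symbol disambiguation

Several greek letters are overloaded across the method; each has its own
config field:

| concept | config field |
|---|---|
| CutMix mixing ratio (lambda) | realized per-call, `MixResult.lam` |
| alignment-loss weight (lambda) | `loss.lambda_align` |
| weight decay (lambda) | `weight_decay` |
| box-loss weight | `lambda_box` |
| fusion modality weight (alpha) | `fusion.alpha_init` (learnable) |
| focal balancing factor (alpha) | `loss.focal_alpha` |

## Notes

- The per-image sensor window length (default 24 h of hourly readings) is a
  documented guess; it is configurable in the generator.
- The single-box regression head exists so IoU-matched mAP@75 is
  exercisable end to end; it is deliberately minimal and desk-scale models
  mostly fail the IoU 0.75 gate even when classifying perfectly.
- `encoder.image.backbone: resnet50` is declared but unavailable offline
  (pretrained weights would be required); use `tinycnn`.
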