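"""Run configuration (strict YAML schema) and reproducibility manifest.

The schema is fail-closed: unknown keys and wrong types are rejected with
an error naming the offending key, because the pipeline has many
hyperparameters whose silent defaulting would be dangerous.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from pathlib import Path
from typing import Dict, List, Literal, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ImageEncoderConfig(_Strict):
    backbone: Literal["tinycnn", "resnet50"] = "tinycnn"
    channels: int = Field(32, ge=1)


class SensorEncoderConfig(_Strict):
    bins: int = Field(6, ge=1)
    layers: int = Field(2, ge=0)
    dim: int = Field(32, ge=1)


class EncoderConfig(_Strict):
    image: ImageEncoderConfig = ImageEncoderConfig()
    sensor: SensorEncoderConfig = SensorEncoderConfig()


class FusionConfig(_Strict):
    mode: Literal["weighted_sum", "weighted_concat", "concat", "bilinear"] = \
        "weighted_concat"
    dim: int = Field(32, ge=1)
    alpha_init: float = Field(0.5, gt=0.0, lt=1.0)


class AttentionConfig(_Strict):
    kind: Literal["none", "self", "cbam", "embedding"] = "embedding"
    layers: int = Field(2, ge=1)


class LossSection(_Strict):
    kind: Literal["ce", "focal", "embedding"] = "embedding"
    lambda_align: float = Field(0.5, ge=0.0)
    focal_gamma: float = Field(2.0, ge=0.0)
    focal_alpha: float = Field(1.0, gt=0.0, le=1.0)
    class_weights: Optional[Union[Literal["inverse_frequency"], List[float]]] = None


class RunConfig(_Strict):
    lr: float = Field(0.001, ge=0.0)  # 0 allowed: "null update" diagnostics
    weight_decay: float = Field(1e-4, ge=0.0)
    batch_size: int = Field(32, ge=1)
    epochs: int = Field(15, ge=1)
    schedule: Literal["cosine", "none"] = "cosine"
    split: Literal["holdout_70_15_15", "cv5"] = "holdout_70_15_15"
    seed: int = 0
    modality: Literal["image", "sensor", "both"] = "both"
    augmentation: List[Literal["cutmix", "mosaic", "gridmask"]] = []
    augment_prob: float = Field(0.5, ge=0.0, le=1.0)
    lambda_box: float = Field(1.0, ge=0.0)
    head_dim: int = Field(32, ge=1)
    encoder: EncoderConfig = EncoderConfig()
    fusion: FusionConfig = FusionConfig()
    attention: AttentionConfig = AttentionConfig()
    loss: LossSection = LossSection()


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration (empty file -> defaults)."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {p}")
    raw = yaml.safe_load(p.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as e:
        msgs = []
        for err in e.errors():
            key = ".".join(str(x) for x in err["loc"]) or "<root>"
            msgs.append(f"key '{key}': {err['msg']} (got {err.get('input')!r})")
        raise ConfigError("invalid configuration: " + "; ".join(msgs)) from e


def config_hash(cfg: RunConfig) -> str:
    """Stable hex digest of the canonicalized configuration."""
    canon = json.dumps(cfg.model_dump(mode="json"), sort_keys=True,
                       separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()


class RunManifest:
    """Reproducibility record written by every CLI subcommand."""

    def __init__(self, command: str, cfg: Optional[RunConfig], seed: int,
                 artifacts: Optional[Dict[str, str]] = None):
        self.command = command
        self.config = cfg.model_dump(mode="json") if cfg is not None else None
        self.config_hash = config_hash(cfg) if cfg is not None else None
        self.seed = seed
        self.seeds = {name: f"{seed}/{name}" for name in
                      ("data", "augmentation", "init", "shuffle")}
        self.start = _dt.datetime.now(_dt.timezone.utc).isoformat()
        self.end: Optional[str] = None
        self.artifacts = artifacts or {}

    def finish(self) -> None:
        self.end = _dt.datetime.now(_dt.timezone.utc).isoformat()

    def to_dict(self) -> dict:
        return {"command": self.command, "config": self.config,
                "config_hash": self.config_hash, "seed": self.seed,
                "seeds": self.seeds, "start": self.start, "end": self.end,
                "artifacts": self.artifacts}

    def write(self, path) -> None:
        if self.end is None:
            self.finish()
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))
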