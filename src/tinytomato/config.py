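"""Run configuration: YAML loading and artifact provenance stamps."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from .boxes import LossConfig
from .errors import ConfigurationError
from .model import ModelSpec
from .train import TrainConfig

__all__ = ["load_run_config", "config_hash", "provenance"]

_SECTIONS = {"model", "loss", "train", "paths", "seed"}


def load_run_config(path) -> dict:
    """Read a YAML run config with optional sections model/loss/train/paths."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _SECTIONS
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
    out = {"raw": raw}
    model_kw = dict(raw.get("model", {}))
    for key in ("strides", "base_channels", "attention_strides"):
        if key in model_kw:
            model_kw[key] = tuple(model_kw[key])
    out["model"] = ModelSpec(**model_kw)
    out["loss"] = LossConfig(**raw.get("loss", {}))
    out["train"] = TrainConfig(**raw.get("train", {}))
    out["paths"] = raw.get("paths", {})
    out["seed"] = int(raw.get("seed", 0))
    return out


def config_hash(obj) -> str:
    """Short stable hash of a config-like structure."""
    return hashlib.sha1(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:12]


def provenance(seed: int, cfg_obj) -> dict:
    return {"seed": seed, "config_hash": config_hash(cfg_obj)}
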