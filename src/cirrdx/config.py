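"""YAML run configuration with profile overlays and paper-default values."""

from __future__ import annotations

import copy
import hashlib
import json
from importlib import resources
from pathlib import Path

import yaml

from .cnn import TrainConfig
from .errors import ConfigurationError
from .preprocess import AugmentConfig
from .serum import SerumConfig

__all__ = ["load_config", "train_config_from", "augment_config_from",
           "serum_config_from", "config_hash"]


def _deep_update(base: dict, overlay: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in overlay.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: str | Path | None = None, profile: str | None = None) -> dict:
    """Defaults, optionally overlaid with a user YAML file and a profile
    block (``ci`` or ``parity``)."""
    text = resources.files("cirrdx.data").joinpath("default_config.yaml").read_text()
    cfg = yaml.safe_load(text)
    if profile:
        profiles = cfg.get("profiles", {})
        if profile not in profiles:
            raise ConfigurationError(f"unknown profile {profile!r}")
        cfg = _deep_update(cfg, profiles.get(profile) or {})
    if path is not None:  # explicit user values win over the profile
        user = yaml.safe_load(Path(path).read_text()) or {}
        cfg = _deep_update(cfg, user)
    return cfg


def train_config_from(cfg: dict, seed: int | None = None) -> TrainConfig:
    t = cfg["train"]
    return TrainConfig(
        lr=t["lr"], weight_decay=t["weight_decay"], batch_size=t["batch_size"],
        dropout=t["dropout"], max_epochs=t["max_epochs"],
        early_stop_patience=t["early_stop_patience"], lr_factor=t["lr_factor"],
        lr_patience=t["lr_patience"], min_lr=t["min_lr"], folds=t["folds"],
        seed=cfg["seed"] if seed is None else seed,
        image_size=t["image_size"],
        sequences=tuple(cfg["preprocess"]["sequences"]),
        base_width=t["base_width"],
    )


def augment_config_from(cfg: dict) -> AugmentConfig:
    a = cfg["augment"]
    return AugmentConfig(
        rotate_deg=tuple(a["rotate_deg"]), zoom=tuple(a["zoom"]),
        contrast_gamma=tuple(a["contrast_gamma"]), noise_sd=a["noise_sd"],
        elastic_alpha=a["elastic_alpha"], elastic_sigma=a["elastic_sigma"],
        apply_prob=a["apply_prob"], enabled=a["enabled"],
    )


def serum_config_from(cfg: dict) -> SerumConfig:
    return SerumConfig(ast_uln=cfg["serum"]["ast_uln"])


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]
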