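"""Experiment configuration: YAML in, validated dataclasses out.

Two built-in profiles ship with the package: ``full`` carries the
published full-scale defaults (16x3x224x224 clips, tau/h/w = 2/16/16, d_model 768,
12/4 encoder/decoder layers, mask ratio 0.85) and ``tiny`` is a CPU-sized
counterpart used by the test-suite and smoke runs.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .mae_core import EncoderConfig, PretrainState
from .tasks_eval import FitOptions, TaskSpec
from .tokenization import CubeGridSpec

__all__ = ["ExperimentConfig", "PROFILES", "validate_config", "load_config",
           "config_hash"]

PROFILES: dict[str, dict] = {
    "full": {
        "grid": {"T": 16, "tau": 2, "H": 224, "h": 16, "W": 224, "w": 16,
                 "d_model": 768},
        "encoder": {"depth": 12, "heads": 12, "mlp_ratio": 4.0,
                    "decoder_depth": 4, "decoder_width": 384,
                    "decoder_heads": 6},
        "pretrain": {"peak_lr": 1e-4, "warmup_fraction": 0.05,
                     "warmup_init_lr": 1e-5, "floor_lr": 0.0,
                     "betas": [0.9, 0.95], "weight_decay": 0.05,
                     "epochs": 30, "batch_size": 8, "mask_ratio": 0.85},
        "finetune": {"epochs": 50, "batch_size": 16, "peak_lr": 1e-3,
                     "betas": [0.9, 0.98], "weight_decay": 1e-3,
                     "use_stf": True, "stf_L": 1024, "augment_flip_p": 0.5},
        "synth": {"n": 100, "T_raw": 64, "H": 224, "W": 224,
                  "cycle_length": 32, "a_ED": 60.0, "b_ED": 40.0,
                  "speckle_sigma": 0.15, "sector_angle": 75.0,
                  "contraction_range": [0.1, 0.6],
                  "split_fractions": [0.7, 0.15, 0.15]},
    },
    "tiny": {
        "grid": {"T": 8, "tau": 2, "H": 32, "h": 8, "W": 32, "w": 8,
                 "d_model": 64},
        "encoder": {"depth": 2, "heads": 4, "mlp_ratio": 2.0,
                    "decoder_depth": 1, "decoder_width": 32,
                    "decoder_heads": 2},
        "pretrain": {"peak_lr": 1e-3, "warmup_fraction": 0.05,
                     "warmup_init_lr": 1e-4, "floor_lr": 0.0,
                     "betas": [0.9, 0.95], "weight_decay": 0.05,
                     "epochs": 5, "batch_size": 8, "mask_ratio": 0.85},
        "finetune": {"epochs": 15, "batch_size": 16, "peak_lr": 2e-3,
                     "betas": [0.9, 0.98], "weight_decay": 1e-3,
                     "use_stf": True, "stf_L": 128, "augment_flip_p": 0.0},
        "synth": {"n": 60, "T_raw": 24, "H": 32, "W": 32,
                  "cycle_length": 12, "a_ED": 10.0, "b_ED": 7.0,
                  "speckle_sigma": 0.12, "sector_angle": 75.0,
                  "contraction_range": [0.1, 0.6],
                  "split_fractions": [0.7, 0.15, 0.15]},
    },
}

_COMMON_DEFAULTS = {
    "task": {"kind": "regression", "target": "LV_EF", "log_scale": False,
             "ef_threshold": None, "n_classes": 2},
    "seeds": {"data": 0, "model": 0, "train": 0},
    "data": {"manifest": None},
    "out_dir": "out",
}


@dataclass
class ExperimentConfig:
    profile: str
    grid: CubeGridSpec
    encoder: EncoderConfig
    pretrain: PretrainState
    finetune: FitOptions
    task: TaskSpec
    synth: dict
    seeds: dict
    manifest: str | None
    out_dir: Path
    raw: dict = field(repr=False, default_factory=dict)

    @property
    def hash(self) -> str:
        return config_hash(self.raw)


def config_hash(raw: dict) -> str:
    return hashlib.sha256(
        json.dumps(raw, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def validate_config(user: dict | None, profile: str = "tiny"
                    ) -> tuple[ExperimentConfig | None, list[str]]:
    """Merge user settings over profile defaults; return (config, errors).

    Every violated invariant is reported with its field path; the config is
    None whenever errors is non-empty.
    """
    errors: list[str] = []
    if profile not in PROFILES:
        return None, [f"profile: unknown profile {profile!r}"]
    merged = _deep_merge(_COMMON_DEFAULTS, _deep_merge(PROFILES[profile],
                                                       user or {}))

    grid = encoder = pretrain = finetune = task = None
    g = merged["grid"]
    try:
        grid = CubeGridSpec(T=int(g["T"]), tau=int(g["tau"]), H=int(g["H"]),
                            h=int(g["h"]), W=int(g["W"]), w=int(g["w"]),
                            d_model=int(g["d_model"]))
    except (ConfigurationError, KeyError, ValueError) as exc:
        errors.append(f"grid: {exc}")
    e = merged["encoder"]
    try:
        encoder = EncoderConfig(depth=int(e["depth"]),
                                d_model=int(g["d_model"]),
                                heads=int(e["heads"]),
                                mlp_ratio=float(e["mlp_ratio"]),
                                decoder_depth=int(e["decoder_depth"]),
                                decoder_width=int(e["decoder_width"]),
                                decoder_heads=int(e["decoder_heads"]))
    except Exception as exc:
        errors.append(f"encoder: {exc}")
    p = merged["pretrain"]
    try:
        if not 0.0 <= float(p["mask_ratio"]) < 1.0:
            raise ConfigurationError(
                f"mask_ratio must be in [0, 1), got {p['mask_ratio']}")
        pretrain = PretrainState(
            peak_lr=float(p["peak_lr"]), warmup_fraction=float(p["warmup_fraction"]),
            warmup_init_lr=float(p["warmup_init_lr"]), floor_lr=float(p["floor_lr"]),
            betas=tuple(p["betas"]), weight_decay=float(p["weight_decay"]),
            epochs=int(p["epochs"]), batch_size=int(p["batch_size"]),
            mask_ratio=float(p["mask_ratio"]),
            mask_mode=str(p.get("mask_mode", "uniform")),
            per_cube_norm=bool(p.get("per_cube_norm", False)),
            seed=int(merged["seeds"]["train"]))
    except Exception as exc:
        errors.append(f"pretrain: {exc}")
    f = merged["finetune"]
    try:
        finetune = FitOptions(
            epochs=int(f["epochs"]), batch_size=int(f["batch_size"]),
            peak_lr=float(f["peak_lr"]), betas=tuple(f["betas"]),
            weight_decay=float(f["weight_decay"]), use_stf=bool(f["use_stf"]),
            stf_L=int(f["stf_L"]), seed=int(merged["seeds"]["train"]),
            augment_flip_p=float(f["augment_flip_p"]))
    except Exception as exc:
        errors.append(f"finetune: {exc}")
    t = merged["task"]
    try:
        task = TaskSpec(kind=t["kind"], target=t["target"],
                        log_scale=bool(t["log_scale"]),
                        ef_threshold=t["ef_threshold"],
                        n_classes=int(t["n_classes"]))
    except Exception as exc:
        errors.append(f"task: {exc}")

    if errors:
        return None, errors
    return ExperimentConfig(
        profile=profile, grid=grid, encoder=encoder, pretrain=pretrain,
        finetune=finetune, task=task, synth=merged["synth"],
        seeds=merged["seeds"], manifest=merged["data"]["manifest"],
        out_dir=Path(merged["out_dir"]), raw=merged), []


def load_config(path=None, profile: str = "tiny") -> ExperimentConfig:
    """Load a YAML config file (or defaults) and raise on any violation."""
    user: dict = {}
    if path is not None:
        text = Path(path).read_text()
        user = yaml.safe_load(text) or {}
        if not isinstance(user, dict):
            raise ConfigurationError(f"{path}: top level must be a mapping")
        profile = user.pop("profile", profile)
    cfg, errors = validate_config(user, profile=profile)
    if errors:
        raise ConfigurationError("; ".join(errors))
    return cfg
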