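"""Validated run configuration and run manifests.

A run config (YAML or JSON) declares the world (or input files), model
sizes, stage list and seeds. Validation is strict: unknown keys are
rejected and defaults are echoed back so the manifest records the full
effective configuration. The manifest also records content hashes of every
artifact a stage writes, so a resumed run can verify its inputs.
"""

from __future__ import annotations

import hashlib
import json
import os
from datetime import datetime, timezone

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .model import ModelConfig
from .pipeline import TrainSettings
from .synthetic import SyntheticWorldConfig

STAGES = ("simulate", "pretrain", "metatrain", "finetune", "evaluate")


class WorldSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_drugs: int = 40
    n_cell_lines: int = 15
    samples_per_cell_line: int = 120
    shared_weight: float = 0.8
    cellline_similarity: float = 0.5
    noise_sd: float = 0.1
    dispersion_range: tuple[float, float] | None = (0.5, 1.5)
    expression_noise_sd: float = 0.05

    def build(self, seed: int) -> SyntheticWorldConfig:
        return SyntheticWorldConfig(seed=seed, **self.model_dump())


class ModelSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    gcn_dims: tuple[int, int, int] = (32, 32, 64)
    cnn_channels: tuple[int, ...] = (4, 8)
    fd_hidden: int = 48
    fd_out: int = 24
    fc_out: int = 24
    head_hidden: int = 48
    dropout: float = Field(default=0.1, ge=0.0, lt=1.0)
    alpha: float = Field(default=0.01, gt=0.0)
    beta: float = Field(default=0.001, gt=0.0)
    inner_steps: int = Field(default=1, ge=1)
    first_order: bool = False

    def build(self) -> ModelConfig:
        return ModelConfig(**self.model_dump())


class TrainSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pretrain_epochs: int = Field(default=30, ge=0)
    batch_size: int = Field(default=128, ge=1)
    pretrain_lr: float = Field(default=1e-3, gt=0.0)
    episodes: int = Field(default=300, ge=0)
    N: int = Field(default=5, ge=1)
    K: int = Field(default=10, ge=1)
    Q: int = Field(default=10, ge=1)
    zero_shot: bool = False
    outer_optimizer: str = "sgd"
    supervised_epochs: int | None = None

    @field_validator("outer_optimizer")
    @classmethod
    def _check_opt(cls, v):
        if v not in ("sgd", "adam"):
            raise ValueError("outer_optimizer must be 'sgd' or 'adam'")
        return v

    def build(self) -> TrainSettings:
        return TrainSettings(**self.model_dump())


class EvalSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mode: str = "fewshot"  # fewshot | zeroshot | lowsim | ablation
    split_fraction: float = Field(default=0.8, gt=0.0, lt=1.0)
    n_tasks: int = Field(default=10, ge=1)
    repeats: int = Field(default=20, ge=1)
    threshold: float = 0.0
    variants: list[str] = Field(default_factory=list)

    @field_validator("mode")
    @classmethod
    def _check_mode(cls, v):
        if v not in ("fewshot", "zeroshot", "lowsim", "ablation"):
            raise ValueError(f"unknown evaluation mode {v!r}")
        return v


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    stages: list[str] = Field(default_factory=lambda: list(STAGES))
    seed: int = 0
    ablation: str = "none"
    world: WorldSection = Field(default_factory=WorldSection)
    model: ModelSection = Field(default_factory=ModelSection)
    train: TrainSection = Field(default_factory=TrainSection)
    evaluate: EvalSection = Field(default_factory=EvalSection)

    @field_validator("stages")
    @classmethod
    def _check_stages(cls, v):
        bad = [s for s in v if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages {bad}; allowed: {list(STAGES)}")
        return v

    @field_validator("ablation")
    @classmethod
    def _check_ablation(cls, v):
        allowed = ("none", "no_ml", "no_ft", "no_so", "no_pt")
        if v not in allowed:
            raise ValueError(f"ablation must be one of {allowed}")
        return v


def load_config(path: str) -> RunConfig:
    """Load and validate a YAML/JSON run config; unknown keys are errors."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def file_hash(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    """Record of one run: effective config, seeds, artifacts with hashes."""

    def __init__(self, config: RunConfig, out_dir: str):
        from . import __version__

        self.out_dir = out_dir
        self.doc = {
            "package_version": __version__,
            "created": datetime.now(timezone.utc).isoformat(),
            "config": config.model_dump(),
            "seed": config.seed,
            "artifacts": {},
            "stages_completed": [],
        }

    def record_artifact(self, name: str, path: str):
        self.doc["artifacts"][name] = {
            "path": os.path.relpath(path, self.out_dir),
            "sha256": file_hash(path),
        }

    def complete_stage(self, stage: str):
        self.doc["stages_completed"].append(stage)

    def verify_artifact(self, name: str) -> str:
        """Return the artifact path, checking existence and hash."""
        entry = self.doc["artifacts"].get(name)
        if entry is None:
            raise FileNotFoundError(f"manifest has no artifact {name!r}")
        path = os.path.join(self.out_dir, entry["path"])
        if not os.path.exists(path):
            raise FileNotFoundError(f"artifact {name!r} missing at {path}")
        if file_hash(path) != entry["sha256"]:
            raise ValueError(f"artifact {name!r} hash mismatch at {path}")
        return path

    def save(self, path: str | None = None) -> str:
        path = path or os.path.join(self.out_dir, "manifest.json")
        with open(path, "w") as fh:
            json.dump(self.doc, fh, indent=2)
        return path

    @classmethod
    def load(cls, out_dir: str) -> "RunManifest":
        with open(os.path.join(out_dir, "manifest.json")) as fh:
            doc = json.load(fh)
        obj = cls.__new__(cls)
        obj.out_dir = out_dir
        obj.doc = doc
        return obj


CHECKPOINT_FORMAT_VERSION = 1


def save_checkpoint(state, path: str) -> None:
    """Text checkpoint with explicit theta_E / theta_p grouping."""
    doc = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "stage": state.stage,
        "ablation": state.ablation,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in state.config.__dict__.items()
        },
        "theta_E": {
            k: state.params[k].data.tolist() for k in state.theta_E_keys()
        },
        "theta_p": {
            k: state.params[k].data.tolist() for k in state.theta_p_keys()
        },
        "bn_running": {k: v.tolist() for k, v in state.bn_running.items()},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_checkpoint(path: str):
    import numpy as np

    from . import autodiff as ad
    from .model import ModelState

    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format_version") != CHECKPOINT_FORMAT_VERSION:
        raise ValueError(
            f"checkpoint format {doc.get('format_version')!r} not supported "
            f"(expected {CHECKPOINT_FORMAT_VERSION})"
        )
    cfg_raw = {
        k: (tuple(v) if isinstance(v, list) else v) for k, v in doc["config"].items()
    }
    params = {
        k: ad.parameter(np.array(v))
        for group in ("theta_E", "theta_p")
        for k, v in doc[group].items()
    }
    state = ModelState(
        config=ModelConfig(**cfg_raw),
        params=params,
        bn_running={k: np.array(v) for k, v in doc["bn_running"].items()},
        stage=doc["stage"],
        ablation=doc["ablation"],
    )
    state.check_partition()
    return state
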