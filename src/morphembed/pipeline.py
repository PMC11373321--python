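"""Run configuration, seed fan-out and reproducibility manifests.

A run is configured by a YAML file with nested blocks (preprocess, augment,
encoder, pretrain, eval, paths) plus one global seed.  Unknown keys are
rejected.  The global seed fans out to per-stage seeds through a split
sequence, so each stage is reproducible independently of the others.
Every artifact directory receives a ``manifest.json`` recording the config,
the stage seed and checksums of the inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .augment import AugmentationConfig
from .encoder import EncoderConfig
from .finetune_eval import FinetuneConfig
from .pretrain import PretrainConfig

_STAGES = ("simulate", "preprocess", "pretrain", "embed", "knn",
           "finetune", "morphometrics")


@dataclass
class PreprocessOptions:
    prune_axon: bool = True
    downsample: int | None = None


@dataclass
class EvalOptions:
    k: int = 5
    n_seeds: int = 5
    split: float = 0.7


@dataclass
class RunConfig:
    seed: int = 0
    preprocess: PreprocessOptions = field(default_factory=PreprocessOptions)
    augment: AugmentationConfig = field(default_factory=AugmentationConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    pretrain: PretrainConfig = field(default_factory=PretrainConfig)
    finetune: FinetuneConfig = field(default_factory=FinetuneConfig)
    eval: EvalOptions = field(default_factory=EvalOptions)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed split from the global seed."""
        i = _STAGES.index(stage)
        child = np.random.SeedSequence(self.seed).spawn(len(_STAGES))[i]
        return int(child.generate_state(1)[0] % 2 ** 31)


class ConfigError(ValueError):
    """Raised when a config file has unknown or ill-typed keys."""


def _build_block(cls, block: dict, name: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - known
    if unknown:
        raise ConfigError(f"block {name!r}: unknown keys {sorted(unknown)}")
    coerced = {}
    for key, value in block.items():
        if isinstance(value, list):
            value = tuple(value)
        coerced[key] = value
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"block {name!r}: {exc}") from None


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    blocks = {"preprocess": PreprocessOptions, "augment": AugmentationConfig,
              "encoder": EncoderConfig, "pretrain": PretrainConfig,
              "finetune": FinetuneConfig, "eval": EvalOptions}
    unknown = set(raw) - set(blocks) - {"seed"}
    if unknown:
        raise ConfigError(f"unknown top-level keys {sorted(unknown)}")
    kwargs = {"seed": int(raw.get("seed", 0))}
    for name, cls in blocks.items():
        kwargs[name] = _build_block(cls, raw.get(name, {}) or {}, name)
    return RunConfig(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str | Path, stage: str, config: dict, seed: int,
                   inputs: list[str | Path] = ()) -> Path:
    """Record everything needed to reproduce an artifact directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "inputs": {str(p): _sha256(Path(p)) for p in inputs
                   if Path(p).is_file()},
        "versions": {"numpy": np.__version__},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
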