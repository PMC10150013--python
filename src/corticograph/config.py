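"""YAML pipeline configuration with strict validation.

Defaults equal the decoding recipe's stated settings: ordinal embedding
n=5, tau=1; edge retention q=0.25; six 0.5 s segments; 4:1 train/test
split; GIN with 64 hidden channels, 2-layer MLPs, Adam lr 0.005, 300
epochs, batch size 128.  Unknown keys are rejected so a typo cannot
silently fall back to a default.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = [
    "SimulateConfig", "PreprocessConfig", "GraphConfig", "TrainConfig",
    "PipelineConfig", "config_hash",
]


def _build(cls, data: dict, section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown key(s) in config section '{section}': {sorted(unknown)}"
        )
    return cls(**data)


@dataclass
class SimulateConfig:
    n_per_class: int = 15
    subjects: list[str] = field(default_factory=lambda: ["S01", "S02"])
    patient_subjects: list[str] = field(default_factory=list)
    noise_sd: float = 1.0
    coupling: float = 1.5
    patient_noise_sd: float = 10.0
    patient_coupling_scale: float = 0.25


@dataclass
class PreprocessConfig:
    n_segments: int = 6
    segment_seconds: float = 0.5
    train_ratio: int = 4
    test_ratio: int = 1
    skip_ica: bool = True


@dataclass
class GraphConfig:
    n: int = 5          # ordinal embedding dimension
    tau: int = 1        # ordinal time lag
    q: float = 0.25     # fraction of strongest SPMI pairs kept as edges


@dataclass
class TrainConfig:
    num_layers: int = 3
    hidden: int = 64
    epochs: int = 300
    batch_size: int = 128
    learning_rate: float = 0.005
    movement_loss_weight: float = 1.0


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    graph: GraphConfig = field(default_factory=GraphConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        sections = {
            "simulate": SimulateConfig,
            "preprocess": PreprocessConfig,
            "graph": GraphConfig,
            "train": TrainConfig,
        }
        kwargs = {}
        for name, section_cls in sections.items():
            kwargs[name] = _build(section_cls, data.pop(name, {}), name)
        seed = data.pop("seed", 0)
        if data:
            raise ValueError(f"unknown top-level config key(s): {sorted(data)}")
        return cls(seed=seed, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return asdict(self)


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash of the full configuration, for artifact manifests."""
    canonical = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_default_config(path) -> None:
    Path(path).write_text(yaml.safe_dump(PipelineConfig().to_dict()))
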