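"""YAML run configuration with strict (unknown-keys-rejected) parsing."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .model import ModelConfig
from .training import TrainConfig

__all__ = ["DataConfig", "RunConfig", "load_run_config", "save_run_config"]


def _from_mapping(cls, mapping: dict, where: str):
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {sorted(unknown)}")
    return cls(**mapping)


@dataclass
class DataConfig:
    """Either file paths or a generator spec for the training inputs."""
    kind: str = "multitask"          # multitask | chiral | equilibrium
    n_molecules: int = 200
    n_tasks: int = 4
    coverage: float = 0.5
    sigma: float = 0.3
    seed: int = 0
    conformers: str | None = None    # SDF/XYZ path (overrides the generator)
    labels: str | None = None        # CSV (mol_id, task_id, value)
    task_meta: str | None = None     # CSV task meta table

    def __post_init__(self):
        if self.kind not in ("multitask", "chiral", "equilibrium"):
            raise ValueError(f"unknown data kind {self.kind!r}")


@dataclass
class RunConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    data: DataConfig = field(default_factory=DataConfig)
    output_dir: str = "runs/default"

    def to_dict(self) -> dict:
        return {"model": asdict(self.model), "training": asdict(self.training),
                "data": asdict(self.data), "output_dir": self.output_dir}


def load_run_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - {"model", "training", "data", "output_dir"}
    if unknown:
        raise ValueError(f"unknown top-level key(s): {sorted(unknown)}")
    return RunConfig(
        model=_from_mapping(ModelConfig, raw.get("model", {}), "model"),
        training=_from_mapping(TrainConfig, raw.get("training", {}), "training"),
        data=_from_mapping(DataConfig, raw.get("data", {}), "data"),
        output_dir=raw.get("output_dir", "runs/default"))


def save_run_config(path, cfg: RunConfig) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
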