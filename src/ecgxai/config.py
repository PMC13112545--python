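"""Run configuration: every stage's parameters in one serializable object.

``RunConfig`` nests the per-stage dataclasses and round-trips losslessly
through YAML, so a whole analysis is reproducible from one text file plus
a seed.  CLI flags override individual keys.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Dict

import yaml

from .model import ModelConfig, TrainConfig
from .preprocessing import PreprocConfig
from .records import Rhythm
from .synth import NoiseConfig, SynthConfig

__all__ = ["XaiConfig", "GradCamConfig", "EvalConfig", "RunConfig"]


@dataclass(frozen=True)
class XaiConfig:
    method: str = "lime"
    n_perturbations: int = 500
    n_coalitions: int = 1000
    kernel_width: float = 0.25
    background: str = "zeros"
    segment_length_s: float = 0.1


@dataclass(frozen=True)
class GradCamConfig:
    layer_id: int | None = None
    threshold_quantile: float = 0.8


@dataclass(frozen=True)
class EvalConfig:
    train_fraction: float = 0.9
    k_folds: int = 10
    decision_threshold: float = 0.5


@dataclass(frozen=True)
class SimulateConfig:
    n: int = 20
    class_balance: float = 0.5
    duration: float = 30.0
    fs: float = 300.0


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    preprocessing: PreprocConfig = field(default_factory=PreprocConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    xai: XaiConfig = field(default_factory=XaiConfig)
    gradcam: GradCamConfig = field(default_factory=GradCamConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        data = asdict(self)
        data["preprocessing"]["median_durations"] = list(
            data["preprocessing"]["median_durations"]
        )
        path.write_text(yaml.safe_dump(data, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Dict[str, Any]) -> "RunConfig":
        sub_classes = {
            "simulate": SimulateConfig,
            "preprocessing": PreprocConfig,
            "model": ModelConfig,
            "train": TrainConfig,
            "xai": XaiConfig,
            "gradcam": GradCamConfig,
            "evaluation": EvalConfig,
        }
        kwargs: Dict[str, Any] = {}
        for f in fields(cls):
            if f.name not in data:
                continue
            value = data[f.name]
            if f.name == "seed":
                kwargs["seed"] = int(value)
                continue
            if f.name == "preprocessing" and "median_durations" in value:
                value = dict(value, median_durations=tuple(value["median_durations"]))
            kwargs[f.name] = sub_classes[f.name](**value)
        return cls(**kwargs)

    def override(self, **updates: Any) -> "RunConfig":
        return replace(self, **updates)
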