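"""Run configuration: one YAML file mirroring every stage's parameters.

Each documented constant of the method appears exactly once, in the
dataclass default of its owning module: the red-channel threshold scale
``a = 0.5``, 64-px patches, opening radii 20 (mining) and 5
(post-processing), loss weights ``w1 = 1``/``w2 = 0.1`` with ``eps = 1``,
mini-batches of 4, quality gates roundness > 0.7 and solidity > 0.9, the
20 % gain rule, detection threshold ``T = 0.5`` and at most 3 recursive
iterations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .losses import LossConfig
from .model import UNetConfig
from .recursive import RecursionConfig
from .sample_prep import NegativeMiningConfig
from .synth import SynthConfig
from .train import TrainConfig

__all__ = ["DataConfig", "EvalConfig", "RunConfig"]


@dataclass
class DataConfig:
    """How many tiles to generate and which fraction carries annotations."""

    n_images: int = 20
    n_test_images: int = 10
    annotation_fraction: float = 0.25
    negatives_per_image: int = 4

    def __post_init__(self) -> None:
        if not 0.0 <= self.annotation_fraction <= 1.0:
            raise ValueError("annotation_fraction must be in [0, 1]")


@dataclass
class EvalConfig:
    detection_threshold: float = 0.5
    strict: bool = False  # ">= T" by default; ">" when strict


def _build(cls, data: dict):
    if data is None:
        return cls()
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = dict(data)
    if cls is SynthConfig and "axis_ratio_range" in kwargs:
        kwargs["axis_ratio_range"] = tuple(kwargs["axis_ratio_range"])
    return cls(**kwargs)


@dataclass
class RunConfig:
    """Nested configuration for the full pipeline, plus paths and a seed.

    Every stochastic stage derives its stream from ``seed`` and a stage tag,
    so one integer reproduces the entire pipeline.
    """

    seed: int = 0
    workdir: str = "renuseg-run"
    data: DataConfig = field(default_factory=DataConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    mining: NegativeMiningConfig = field(default_factory=NegativeMiningConfig)
    unet: UNetConfig = field(default_factory=UNetConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    recursion: RecursionConfig = field(default_factory=RecursionConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)

    _SECTIONS = {
        "data": DataConfig,
        "synth": SynthConfig,
        "mining": NegativeMiningConfig,
        "unet": UNetConfig,
        "loss": LossConfig,
        "train": TrainConfig,
        "recursion": RecursionConfig,
        "evaluation": EvalConfig,
    }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        kwargs = {}
        for key, sub in cls._SECTIONS.items():
            if key in data:
                section = data.pop(key)
                if key == "train" and section and "loss" in section:
                    section = dict(section)
                    section["loss"] = _build(LossConfig, section["loss"])
                kwargs[key] = _build(sub, section)
        for key in ("seed", "workdir"):
            if key in data:
                kwargs[key] = data.pop(key)
        if data:
            raise ValueError(f"unknown configuration keys: {sorted(data)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def resolve(self, *parts) -> Path:
        return Path(self.workdir).joinpath(*parts)
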