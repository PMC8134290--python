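"""Strict YAML run configuration.

One nested document drives every command; unknown keys are rejected so a
typo cannot silently fall back to a default.  All randomness descends from
the single root ``seed``, fanned out with fixed per-module offsets.
"""

from __future__ import annotations

import dataclasses
import typing
from dataclasses import dataclass, field

import yaml

from .depth_net import DepthNetConfig
from .simulator import AirwaySceneParams
from .style_transfer import StyleTransferConfig

__all__ = ["RunConfig", "TrajectoryConfig", "ImageConfig", "load_config"]


def _from_mapping(cls, d: dict, path: str):
    if not isinstance(d, dict):
        raise ValueError(f"{path}: expected a mapping, got {type(d).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
    hints = typing.get_type_hints(cls)
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        ftype = hints.get(f.name, f.type)
        if dataclasses.is_dataclass(ftype) and isinstance(v, dict):
            v = _from_mapping(ftype, v, f"{path}.{f.name}")
        elif isinstance(v, list) and f.name in ("image_size", "input_size", "betas", "albedo"):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


@dataclass
class TrajectoryConfig:
    n_frames: int = 300
    speed: float = 2.5  # mm/s
    sample_rate: float = 50.0  # Hz
    mode: str = "forward"
    jitter_translation: float = 0.15
    jitter_rotation: float = 0.03


@dataclass
class ImageConfig:
    width: int = 64
    height: int = 64
    fov_deg: float = 80.0


@dataclass
class RunConfig:
    seed: int = 0
    scene: AirwaySceneParams = field(default_factory=AirwaySceneParams)
    trajectory: TrajectoryConfig = field(default_factory=TrajectoryConfig)
    image: ImageConfig = field(default_factory=ImageConfig)
    style_transfer: StyleTransferConfig = field(default_factory=StyleTransferConfig)
    depth_net: DepthNetConfig = field(default_factory=DepthNetConfig)

    # fixed per-module seed offsets (all randomness flows from `seed`)
    @property
    def scene_seed(self) -> int:
        return self.seed

    @property
    def trajectory_seed(self) -> int:
        return self.seed + 1000

    @property
    def style_seed(self) -> int:
        return self.seed + 2000

    @property
    def depth_seed(self) -> int:
        return self.seed + 3000

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def load_config(path_or_none, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config (or defaults) and apply flat overrides."""
    doc: dict = {}
    if path_or_none is not None:
        with open(path_or_none) as fh:
            doc = yaml.safe_load(fh) or {}
    cfg = _from_mapping(RunConfig, doc, "config")
    if overrides:
        for key, value in overrides.items():
            obj = cfg
            *parents, leaf = key.split(".")
            for p in parents:
                obj = getattr(obj, p)
            if not hasattr(obj, leaf):
                raise ValueError(f"unknown override key {key!r}")
            setattr(obj, leaf, value)
    return cfg
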