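"""Nested pipeline configuration with YAML round-tripping.

Every tunable named in the stage modules lives here with its default, so a
run is fully described by one ``PipelineConfig``.  Loading rejects unknown
keys (naming the offending path) rather than silently ignoring typos.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, is_dataclass
from pathlib import Path

import yaml

__all__ = [
    "BilateralConfig", "GammaConfig", "EnhancementConfig", "SegmentationConfig",
    "RefineConfig", "BaselinesConfig", "PipelineConfig",
]


@dataclass
class BilateralConfig:
    spatial_sigma: float = 3.0
    range_sigma: float = 0.1
    window_radius: int = 6


@dataclass
class GammaConfig:
    convention: str = "equations"  # equations | prose
    max: float = 5.0


@dataclass
class EnhancementConfig:
    bilateral: BilateralConfig = field(default_factory=BilateralConfig)
    gamma: GammaConfig = field(default_factory=GammaConfig)


@dataclass
class SegmentationConfig:
    class_index: int = 0  # darkest class = nuclei
    grayscale_weights: tuple = (0.299, 0.587, 0.114)


@dataclass
class RefineConfig:
    a_min_fraction: float = 0.001  # of image area
    open_radius: int = 2
    close_radius: int = 3
    jaggedness_threshold: float = 1.15
    hole_area: int = 10
    edge_method: str = "off"
    background_connectivity: int = 4


@dataclass
class BaselinesConfig:
    window_radius: int = 15
    bradley_k: float = 12.0
    niblack_k: float = -0.2
    nick_k: float = -0.13
    sauvola_k: float = 0.1
    sauvola_r: float = 128.0
    feng_alpha1: float = 0.12
    feng_gamma: float = 2.0
    feng_k1: float = 0.25
    feng_k2: float = 0.04
    feng_secondary_scale: int = 2


@dataclass
class PipelineConfig:
    enhancement: EnhancementConfig = field(default_factory=EnhancementConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    refine: RefineConfig = field(default_factory=RefineConfig)
    baselines: BaselinesConfig = field(default_factory=BaselinesConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["segmentation"]["grayscale_weights"] = list(self.segmentation.grayscale_weights)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _build(cls, data, path="")

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)


def _build(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ValueError(f"config section {path or '<root>'} must be a mapping")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        where = f"{path}.{sorted(unknown)[0]}" if path else sorted(unknown)[0]
        raise ValueError(f"unknown config key: {where}")
    kwargs = {}
    for name, f in known.items():
        if name not in data:
            continue
        sub = f.type if isinstance(f.type, type) else None
        default = getattr(cls(), name)
        if is_dataclass(default):
            kwargs[name] = _build(type(default), data[name], f"{path}.{name}" if path else name)
        elif name == "grayscale_weights":
            kwargs[name] = tuple(data[name])
        else:
            kwargs[name] = data[name]
    return cls(**kwargs)
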