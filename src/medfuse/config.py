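"""Fusion pipeline configuration.

Groups every tunable of the pipeline with the published defaults: the
choose-max segmentation threshold 0.5, the 8x8 consistency window, the 16x16
scoring block, guided-filter r = 4 / eps = 0.1, the 3x3 local-energy
template with salience threshold T = 0.5, and the SGD hyperparameters of the
clarity network.  Configs round-trip through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace

import numpy as np
import yaml

from .hf_fusion import NetworkConfig
from .lf_fusion import EnergyConfig

__all__ = ["FusionConfig", "PreprocessSettings", "LsistSettings", "HfSettings"]


@dataclass(frozen=True)
class PreprocessSettings:
    shape: str = "disk"  # structuring element shape: disk | square
    radius: int | None = None  # None -> 9 at 256 px, scaled with image size
    variant: str = "classic"  # classic | residue


@dataclass(frozen=True)
class LsistSettings:
    scales: int = 3
    directions: tuple = (8, 8, 16)  # coarse -> fine
    boundary: str = "periodic"  # periodic | symmetric (pre-padding)
    pad: int = 16  # symmetric pre-padding width, pixels

    def __post_init__(self):
        object.__setattr__(self, "directions", tuple(self.directions))


@dataclass(frozen=True)
class HfSettings:
    per_band: bool = True  # one decision map per (scale, direction) band
    guided_r: int = 4
    guided_eps: float = 0.1
    segment_threshold: float = 0.5
    consistency_window: int = 8
    chunk: int = 4  # bands scored per CNN batch


@dataclass(frozen=True)
class FusionConfig:
    preprocess: PreprocessSettings = field(default_factory=PreprocessSettings)
    grayspca_enabled: bool = True
    lsist: LsistSettings = field(default_factory=LsistSettings)
    hf: HfSettings = field(default_factory=HfSettings)
    lf: EnergyConfig = field(default_factory=EnergyConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    normalization: str = "anchored"  # anchored | minmax | clip | none
    metrics_on: str = "preprocessed"  # preprocessed | raw
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lf"]["template"] = np.asarray(self.lf.template).tolist()
        d["lsist"]["directions"] = list(self.lsist.directions)
        d["network"]["conv_filters"] = list(self.network.conv_filters)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FusionConfig":
        d = dict(d)
        parts = {}
        for name, sub_cls in (
            ("preprocess", PreprocessSettings),
            ("lsist", LsistSettings),
            ("hf", HfSettings),
            ("lf", EnergyConfig),
            ("network", NetworkConfig),
        ):
            if name in d:
                sub = dict(d.pop(name))
                if name == "lsist" and "directions" in sub:
                    sub["directions"] = tuple(sub["directions"])
                if name == "lf" and "template" in sub:
                    sub["template"] = np.asarray(sub["template"], dtype=float)
                if name == "network" and "conv_filters" in sub:
                    sub["conv_filters"] = tuple(sub["conv_filters"])
                known = {f.name for f in fields(sub_cls)}
                parts[name] = sub_cls(**{k: v for k, v in sub.items() if k in known})
        known = {f.name for f in fields(cls)}
        return cls(**parts, **{k: v for k, v in d.items() if k in known})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FusionConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def with_(self, **kw) -> "FusionConfig":
        return replace(self, **kw)
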