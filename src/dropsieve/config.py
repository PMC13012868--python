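"""Run configuration: every tunable of the pipeline in one serialisable record.

The config is written verbatim (plus its SHA-256 hash) into every output the
pipeline produces, so any table can be traced back to the exact parameters
that generated it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .granulometry import DiameterSchedule

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # preprocessing
    resize_factor: float = 0.5
    ball_radius_px: Optional[float] = None  # None -> 2 * schedule x_max
    # sieving schedule (applied to the resized image)
    x_min: float = 2.0
    x_max: float = 50.0
    dx: float = 2.0
    area_formula: str = "printed"  # 2*pi*(x/2)^2; "circle" -> pi*(x/2)^2
    # segmentation
    threshold_method: str = "pooled_otsu"  # or "otsu", "fixed"
    fixed_threshold: Optional[float] = None
    min_area_px2: float = 4.0
    connectivity: int = 2  # skimage convention: 2 == 8-connectivity in 2D
    # hit calling / titration
    z_cut: float = 3.0
    frac_of_max: float = 0.1
    # reproducibility & paths
    seed: int = 0
    images_dir: str = ""
    platemap: str = ""
    output_dir: str = "out"

    def __post_init__(self) -> None:
        if not (0 < self.resize_factor <= 1):
            raise ValueError("resize_factor must be in (0, 1]")
        if self.ball_radius_px is not None and self.ball_radius_px < 1:
            raise ValueError("ball_radius_px must be >= 1")
        if self.min_area_px2 < 0 or self.z_cut <= 0 or not (0 < self.frac_of_max <= 1):
            raise ValueError("invalid segmentation/hit-calling parameters")

    @property
    def ball_radius(self) -> float:
        return self.ball_radius_px if self.ball_radius_px is not None else 2.0 * self.x_max

    def schedule(self) -> DiameterSchedule:
        return DiameterSchedule.uniform(self.x_min, self.x_max, self.dx, self.area_formula)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        """SHA-256 of the canonical JSON serialisation (paths included)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()
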