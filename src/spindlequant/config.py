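"""Reproducible run configuration for the pipeline CLI.

A :class:`RunConfig` carries the modality, the voxel calibration, per-module
parameter blocks and the master seed; it round-trips losslessly through YAML
and hashes canonically so every output can record exactly which configuration
produced it.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml

from .core import InvalidParameterError, OpticsParams


@dataclass
class RunConfig:
    modality: str = "confocal"              # confocal | sted
    pixel_size_xy: float | None = None      # None -> modality default
    z_step: float | None = None
    frame_interval_s: float = 30.0
    axial_scale: float = 0.81
    seed: int = 0
    simulate: dict = field(default_factory=lambda: dict(
        n_pairs=6, spindle_length=12.0, spindle_width=9.0,
        mean_separation=0.98, tilt_spread_deg=10.0, bridging_fraction=1.0,
        depleted=False, bridging_removal_fraction=0.41))
    fiber_quant: dict = field(default_factory=lambda: dict(
        roi_size_px=5, n_k_ref=12.6, noise_floor=0.0))
    end_on: dict = field(default_factory=lambda: dict(
        n_central=10, min_separation=0.3, prominence_fraction=0.10))
    dynamics: dict = field(default_factory=lambda: dict(
        blur_sigma=2.0, line_width_px=10, n_sustained=3, min_rise=0.1))
    error_classify: dict = field(default_factory=lambda: dict(
        stretch_threshold=1.5, lookback_s=30.0))
    overlap: dict = field(default_factory=lambda: dict(base_fraction=0.10))

    def __post_init__(self) -> None:
        if self.modality not in ("confocal", "sted"):
            raise InvalidParameterError("modality must be 'confocal' or 'sted'")

    def optics(self, **overrides) -> OpticsParams:
        base = OpticsParams.sted if self.modality == "sted" else OpticsParams.confocal
        kwargs = dict(axial_scale=self.axial_scale)
        if self.pixel_size_xy is not None:
            kwargs["pixel_size_xy"] = self.pixel_size_xy
        if self.z_step is not None:
            kwargs["z_step"] = self.z_step
        kwargs.update(overrides)
        return base(**kwargs)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
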