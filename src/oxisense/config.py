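"""Structured run configuration with YAML round-tripping and validation.

One config drives every stage of the pipeline; defaults correspond to the
full-scale study conditions (Table-style conductivities, 2 mm mesh,
144 + 32 + 32 = 208 measurements, 12 x 6 scenario targets, 80/10/10 splits,
200 epochs, lr 1e-3, L2 1e-6, 15 dB SNR).  Every stochastic stage carries an
explicit seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """A config file is missing keys or holds invalid values."""


def _from_mapping(cls, data: dict, context: str):
    if not isinstance(data, dict):
        raise ConfigError(f"section '{context}' must be a mapping")
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown keys in '{context}': {sorted(unknown)}")
    return cls(**data)


@dataclass
class GeometryConfig:
    size_x: float = 0.09
    size_y: float = 0.09
    size_z: float = 0.05
    grid_rod_diameter: float = 0.004
    grid_plane_z: float = 0.0
    grid_rod_spacing: float = 0.018
    grid_n_rods: int = 5


@dataclass
class MeshConfig:
    max_h: float = 0.002
    pattern_max_h: float = 0.009  # coarse (even-cell) mesh for pattern selection


@dataclass
class ElectrodeConfig:
    mu_elpos: float = 0.030
    sigma_elpos: float = 0.012
    patch_radius: float = 0.004
    contact_impedance: float = 0.01
    optimized_radial: float = 0.04


@dataclass
class PatternConfig:
    ruleset: str = "default"
    count_volume: int = 144
    count_l1: int = 32
    count_l2: int = 32


@dataclass
class SamplerConfig:
    voxel_size: float = 0.002
    sigma_x: float = 0.045
    sigma_y: float = 0.045
    sigma_z: float = 0.025
    n_sets: int = 12
    targets_per_set: int = 6
    percentile_low: float = 5.0
    percentile_high: float = 98.0
    target_diameter: float = 0.01
    grid_spacing: float = 0.0042


@dataclass
class SurrogateConfig:
    n_random: int = 8000
    width_1: int = 254
    width_2: int = 203
    epochs: int = 200
    lr0: float = 1e-3
    l2: float = 1e-6
    momentum: float = 0.9
    leak: float = 0.01
    batch_size: int = 32
    scaling: str = "minmax"


@dataclass
class DetectorConfig:
    n_positive: int = 3971
    n_negative: int = 3971
    width_1: int = 200
    width_2: int = 100
    epochs: int = 200
    lr0: float = 1e-3
    l2: float = 1e-6
    momentum: float = 0.9
    batch_size: int = 32


@dataclass
class NoiseConfig:
    target_jitter_frac: float = 0.1     # sd = frac * clot conductivity
    background_jitter_frac: float = 0.01  # sd = frac * blood conductivity
    snr_db: float = 15.0


@dataclass
class SeedConfig:
    arrays: int = 1
    targets: int = 2
    dataset: int = 3
    training: int = 4


@dataclass
class RunConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    mesh: MeshConfig = field(default_factory=MeshConfig)
    electrodes: ElectrodeConfig = field(default_factory=ElectrodeConfig)
    pattern: PatternConfig = field(default_factory=PatternConfig)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    surrogate: SurrogateConfig = field(default_factory=SurrogateConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seeds: SeedConfig = field(default_factory=SeedConfig)
    output_dir: str = "runs"

    _SECTIONS = {
        "geometry": GeometryConfig,
        "mesh": MeshConfig,
        "electrodes": ElectrodeConfig,
        "pattern": PatternConfig,
        "sampler": SamplerConfig,
        "surrogate": SurrogateConfig,
        "detector": DetectorConfig,
        "noise": NoiseConfig,
        "seeds": SeedConfig,
    }

    def validate(self) -> None:
        if self.mesh.max_h <= 0 or self.mesh.pattern_max_h <= 0:
            raise ConfigError("mesh.max_h and mesh.pattern_max_h must be > 0")
        if self.noise.snr_db != self.noise.snr_db:
            raise ConfigError("noise.snr_db must be a number")
        for name in ("arrays", "targets", "dataset", "training"):
            if getattr(self.seeds, name) is None:
                raise ConfigError(f"seeds.{name} is required")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping")
        kwargs = {}
        for key, value in data.items():
            if key == "output_dir":
                kwargs[key] = str(value)
            elif key in cls._SECTIONS:
                kwargs[key] = _from_mapping(cls._SECTIONS[key], value, key)
            else:
                raise ConfigError(f"unknown config section '{key}'")
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data or {})
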