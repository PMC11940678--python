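"""Run configuration: YAML in, validated dataclasses out.

The YAML schema mirrors the pipeline stages::

    seed: 1
    output_dir: out
    optics: {pixel_pitch: 2.2, sample_to_sensor: 150.0, ...}
    detection: {expected_ppd_um: 24.0, ...}
    profiling: {n_angles: 36, quorum: 8, ...}
    analysis: {control_label: vehicle, lap_variant: ratio}
    simulate:
      cells_per_image: 25
      n_cells: 150
      groups: {vehicle: 0.0, ASC25: 0.25, ASC50: 0.5, ASC100: 1.0}

Unknown keys anywhere are rejected; every stochastic step derives its
seed from the single top-level seed, which is recorded in the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .detection import DetectionConfig
from .optics import OpticsConfig
from .profiling import ProfilingConfig

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class AnalysisConfig:
    control_label: str = "vehicle"
    lap_variant: str = "ratio"
    qc_threshold_percent: float = 10.0

    def __post_init__(self) -> None:
        if self.lap_variant not in ("ratio", "zscore"):
            raise ValueError("lap_variant must be 'ratio' or 'zscore'")


@dataclass(frozen=True)
class SimulateConfig:
    groups: dict = field(default_factory=lambda: {"vehicle": 0.0, "ASC100": 1.0})
    n_cells: int = 100
    cells_per_image: int = 25

    def __post_init__(self) -> None:
        for label, frac in self.groups.items():
            if not 0.0 <= float(frac) <= 1.0:
                raise ValueError(
                    f"activated fraction of group {label!r} must be in [0, 1]")
        if self.n_cells < 1 or self.cells_per_image < 1:
            raise ValueError("cell counts must be positive")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 1
    output_dir: str = "shadowcyte_out"
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    profiling: ProfilingConfig = field(default_factory=ProfilingConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)


def _build(cls, data: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(
            f"unknown key(s) in {where}: {', '.join(sorted(unknown))}; "
            f"allowed: {', '.join(sorted(names))}")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if f.name == "sensor_shape" and isinstance(v, (list, tuple)):
            v = tuple(int(x) for x in v)
        if f.name == "scale_factors" and isinstance(v, (list, tuple)):
            v = tuple(float(x) for x in v)
        coerced[f.name] = v
    return cls(**coerced)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    ``overrides`` (same nested structure) take precedence; with no path,
    defaults plus overrides are used.
    """
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError("config root must be a mapping")
        data = loaded
    for key, val in (overrides or {}).items():
        if isinstance(val, dict) and isinstance(data.get(key), dict):
            data[key] = {**data[key], **val}
        else:
            data[key] = val
    sections = {"optics": OpticsConfig, "detection": DetectionConfig,
                "profiling": ProfilingConfig, "analysis": AnalysisConfig,
                "simulate": SimulateConfig}
    unknown = set(data) - set(sections) - {"seed", "output_dir"}
    if unknown:
        raise ValueError(f"unknown top-level key(s): {', '.join(sorted(unknown))}")
    kwargs = {}
    for name, cls in sections.items():
        sub = data.get(name, {})
        if not isinstance(sub, dict):
            raise ValueError(f"section {name!r} must be a mapping")
        kwargs[name] = _build(cls, sub, name)
    return RunConfig(seed=int(data.get("seed", 1)),
                     output_dir=str(data.get("output_dir", "shadowcyte_out")),
                     **kwargs)


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the full configuration."""
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
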