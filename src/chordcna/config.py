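"""Pipeline configuration: nested dataclasses with documented defaults,
YAML loading, and strict unknown-key rejection."""

from __future__ import annotations

import dataclasses
from typing import Any

import yaml

from .errors import ConfigError
from .simulate import DEFAULT_DISPERSION, DEFAULT_TOTAL_READS


@dataclasses.dataclass
class GenomeConfig:
    scale: str = "toy"          # "toy" (hg19/10) or "full"
    bin_size: int = 100_000     # bp
    seed: int = 1               # GC-track seed


@dataclasses.dataclass
class SimulationConfig:
    preset: str = "mug-cc1"     # mug-cc1 | primary-tumor | lcl | balanced
    events: list | None = None  # explicit [(region, cn), ...] overrides preset
    sex: str = "XY"
    purity: float | None = None  # None: preset default
    total_reads: int = DEFAULT_TOTAL_READS
    dispersion: float = DEFAULT_DISPERSION
    gc_bias_amplitude: float = 0.30
    gc_bias_peak: float = 0.45
    n_controls: int = 30
    seed: int = 7


@dataclasses.dataclass
class NormalizationConfig:
    lowess_fraction: float = 0.3
    max_zero_fraction: float = 0.10
    center: bool = True


@dataclasses.dataclass
class SegmentationConfig:
    alpha: float = 0.01
    nperm: int = 1000
    min_width: int = 3
    sd_undo: float = 1.0
    seed: int = 0


@dataclasses.dataclass
class CallingConfig:
    gain: float = 0.2
    loss: float = -0.2
    high_level_gain: float = 0.75
    chromosome_fraction: float = 0.9


@dataclasses.dataclass
class PipelineConfig:
    genome: GenomeConfig = dataclasses.field(default_factory=GenomeConfig)
    simulation: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    normalization: NormalizationConfig = dataclasses.field(default_factory=NormalizationConfig)
    segmentation: SegmentationConfig = dataclasses.field(default_factory=SegmentationConfig)
    calling: CallingConfig = dataclasses.field(default_factory=CallingConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTIONS = {
    "genome": GenomeConfig,
    "simulation": SimulationConfig,
    "normalization": NormalizationConfig,
    "segmentation": SegmentationConfig,
    "calling": CallingConfig,
}


def _build(cls, data: dict[str, Any]):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown keys in {cls.__name__}: {sorted(unknown)}")
    return cls(**data)


def config_from_dict(data: dict[str, Any]) -> PipelineConfig:
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = data.get(name, {})
        if not isinstance(section, dict):
            raise ConfigError(f"config section {name!r} must be a mapping")
        kwargs[name] = _build(cls, section)
    return PipelineConfig(**kwargs)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    return config_from_dict(data)
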