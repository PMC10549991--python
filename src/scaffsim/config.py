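"""YAML configuration: one block per model component, every physical
constant appearing exactly once with its reference value as the default."""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import ScaffoldSpec
from .mechanics import OgdenMaterial, OssFieldParams
from .flow import FluidProps, WssFieldParams
from .mechanoreg import PhenotypeThresholds, StimulusParams, ViabilityLimits
from .synthetic import SyntheticFieldSpec

__all__ = ["PipelineConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class LoadingConfig:
    """Loading block: protocol parameters shared across amplitudes."""

    frequency_hz: float = 1.0
    amplitude_fraction: float = 0.10
    dt_s: float = 0.004
    n_cycles: int = 1


@dataclass(frozen=True)
class IOConfig:
    surface_resolution: int = 16
    weighting: str = "node_count"  # or "area"
    evaluate_at: str = "s_max2"


@dataclass(frozen=True)
class PipelineConfig:
    """Bundle of every tunable block of the analysis pipeline."""

    geometry: ScaffoldSpec = field(default_factory=ScaffoldSpec)
    material: OgdenMaterial = field(default_factory=OgdenMaterial)
    fluid: FluidProps = field(default_factory=FluidProps)
    loading: LoadingConfig = field(default_factory=LoadingConfig)
    stimulus: StimulusParams = field(default_factory=StimulusParams)
    thresholds: PhenotypeThresholds = field(default_factory=PhenotypeThresholds)
    viability: ViabilityLimits = field(default_factory=ViabilityLimits)
    oss_field: OssFieldParams = field(default_factory=OssFieldParams)
    wss_field: WssFieldParams = field(default_factory=WssFieldParams)
    synthetic: SyntheticFieldSpec = field(default_factory=SyntheticFieldSpec)
    io: IOConfig = field(default_factory=IOConfig)

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path


_TUPLE_FIELDS = {"mu", "alpha", "d", "wss_window_mpa"}


def _build(cls, data: dict | None):
    if data is None:
        return cls()
    kwargs = {}
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys {sorted(unknown)} in {cls.__name__} config block")
    for key, val in data.items():
        if key in _TUPLE_FIELDS and isinstance(val, list):
            val = tuple(val)
        kwargs[key] = val
    return cls(**kwargs)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a pipeline config from YAML; missing blocks take defaults."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    blocks = {
        "geometry": ScaffoldSpec,
        "material": OgdenMaterial,
        "fluid": FluidProps,
        "loading": LoadingConfig,
        "stimulus": StimulusParams,
        "thresholds": PhenotypeThresholds,
        "viability": ViabilityLimits,
        "oss_field": OssFieldParams,
        "wss_field": WssFieldParams,
        "synthetic": SyntheticFieldSpec,
        "io": IOConfig,
    }
    unknown = set(raw) - set(blocks)
    if unknown:
        raise ValueError(f"unknown config blocks {sorted(unknown)}")
    kwargs = {name: _build(cls, raw.get(name)) for name, cls in blocks.items()}
    return PipelineConfig(**kwargs)


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash of the full configuration (for run logging)."""
    text = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]
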