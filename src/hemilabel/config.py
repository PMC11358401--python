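"""YAML pipeline configuration.

One file can hold a block per stage; every key is optional and falls
back to the stage's default::

    preprocess:
      mask_method: otsu_largest_component
      bias_fwhm_mm: 60.0
      target_spacing_mm: 0.3
    cluster:
      k_min: 4
      k_max: 9
      seed: 0
    fusion:
      closing_radius_mm: 1.2
    mirror:
      alpha: null          # null -> adaptive per image
      crossing_tolerance_mm: 0.5
    synth:
      mean_range: [25, 225]
      std_range: [5, 25]
      thickness_range: [1, 9]
      seed: 0
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .cluster import ContextSetConfig
from .fusion import FusionConfig
from .mirroring import MirrorConfig
from .preprocess import PreprocessConfig
from .synth import SynthConfig

__all__ = ["PipelineConfig", "load_config"]

# YAML key -> dataclass field, where they differ (units spelled out in YAML)
_ALIASES = {
    "bias_fwhm_mm": "bias_fwhm",
    "target_spacing_mm": "target_spacing",
    "closing_radius_mm": "closing_radius",
    "crossing_tolerance_mm": "crossing_tolerance",
}


@dataclasses.dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = dataclasses.field(default_factory=PreprocessConfig)
    cluster: ContextSetConfig = dataclasses.field(default_factory=ContextSetConfig)
    fusion: FusionConfig = dataclasses.field(default_factory=FusionConfig)
    mirror: MirrorConfig = dataclasses.field(default_factory=MirrorConfig)
    synth: SynthConfig = dataclasses.field(default_factory=SynthConfig)


def _build(cls, block: dict):
    kwargs = {}
    fields = {f.name for f in dataclasses.fields(cls)}
    for key, value in (block or {}).items():
        name = _ALIASES.get(key, key)
        if name not in fields:
            raise KeyError(f"unknown config key {key!r} for {cls.__name__}")
        if isinstance(value, list):
            value = tuple(value)
        kwargs[name] = value
    return cls(**kwargs)


def load_config(path) -> PipelineConfig:
    """Read a YAML config file into a :class:`PipelineConfig`."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig(
        preprocess=_build(PreprocessConfig, raw.get("preprocess")),
        cluster=_build(ContextSetConfig, raw.get("cluster")),
        fusion=_build(FusionConfig, raw.get("fusion")),
        mirror=_build(MirrorConfig, raw.get("mirror")),
        synth=_build(SynthConfig, raw.get("synth")),
    )
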