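"""Run configuration: one YAML document covering every tunable parameter.

The document has four optional sections -- ``ransac``, ``drift``, ``sim``
and ``tracking`` -- whose keys map one-to-one onto the corresponding
parameter dataclasses. Unknown sections or keys are rejected so typos
cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .drift import DriftParams
from .ransac import RansacParams
from .simulate import SimParams

__all__ = ["TrackingOptions", "RunConfig", "load_config"]


@dataclass
class TrackingOptions:
    window: int = 2
    coverage_threshold: float = 0.7
    min_track_length: int = 2


@dataclass
class RunConfig:
    ransac: RansacParams = field(default_factory=RansacParams)
    drift: DriftParams = field(default_factory=DriftParams)
    sim: SimParams = field(default_factory=SimParams)
    tracking: TrackingOptions = field(default_factory=TrackingOptions)


_SECTIONS = {
    "ransac": RansacParams,
    "drift": DriftParams,
    "sim": SimParams,
    "tracking": TrackingOptions,
}


def _build(cls, values: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**values)


def load_config(path=None) -> RunConfig:
    """Load a RunConfig from YAML; ``None`` gives all defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"{path}: unknown sections {sorted(unknown)}")
    kwargs = {
        name: _build(cls, raw.get(name, {}) or {})
        for name, cls in _SECTIONS.items()
    }
    return RunConfig(**kwargs)
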