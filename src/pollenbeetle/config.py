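"""YAML (de)serialisation of run configurations.

The configuration file mirrors :class:`pollenbeetle.engine.SimulationConfig`
field for field; nested parameter blocks (life_history, mortality, movement,
phenology, compound) are plain mappings.  Only keys present in the file are
overridden, so a minimal file might set just ``strategy`` and ``years``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .engine import SimulationConfig
from .insecticide import Compound, COMPOUND_PRESETS
from .landscape import CropPhenologyParams
from .dispersal import MovementParams
from .population import LifeHistoryParams, MortalityParams
from .weather import SiteClimate

_NESTED = {
    "life_history": LifeHistoryParams,
    "mortality": MortalityParams,
    "movement": MovementParams,
    "phenology": CropPhenologyParams,
}


def _build_compound(spec) -> Compound:
    if isinstance(spec, str):
        return COMPOUND_PRESETS[spec]
    if isinstance(spec, dict):
        return Compound(**spec)
    return spec


def load_config(path) -> SimulationConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for key, value in raw.items():
        if key in _NESTED:
            kwargs[key] = _NESTED[key](**value)
        elif key == "compound":
            kwargs[key] = _build_compound(value)
        elif key == "site" and isinstance(value, dict):
            kwargs[key] = SiteClimate(**value)
        elif key in ("dims", "composition") and value is not None:
            kwargs[key] = tuple(value) if key == "dims" else dict(value)
        else:
            kwargs[key] = value
    unknown = set(kwargs) - {f.name for f in dataclasses.fields(SimulationConfig)}
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    return SimulationConfig(**kwargs)


def save_config(config: SimulationConfig, path) -> None:
    data = {}
    for f in dataclasses.fields(SimulationConfig):
        value = getattr(config, f.name)
        if dataclasses.is_dataclass(value):
            value = dataclasses.asdict(value)
        elif isinstance(value, tuple):
            value = list(value)
        data[f.name] = value
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
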