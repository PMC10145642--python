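"""Run configuration: defaults, YAML loading/saving, validation.

The defaults are the tuned operating point of the method: 150 particles,
150 iterations, 2 thresholds, position range [0, 255], velocity range
[-5, 5], archive capacity 30, grid size 7, inertia 1.3, acceleration
coefficients 0.5/0.5, mutation rate 0.1, and 1000 requested superpixels.
A single seed governs every source of randomness in a run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import ConfigError
from .fusion import PostprocessConfig
from .mopso import SwarmConfig
from .superpixel import SuperpixelConfig

__all__ = ["ClaheConfig", "RunConfig", "load_config", "save_config"]


@dataclass
class ClaheConfig:
    clip_limit: float = 0.01
    tile_grid: tuple[int, int] = (8, 8)

    def validate(self) -> "ClaheConfig":
        if self.clip_limit <= 0:
            raise ConfigError(f"clahe.clip_limit must be > 0, got {self.clip_limit}")
        if len(self.tile_grid) != 2 or min(self.tile_grid) < 1:
            raise ConfigError(f"clahe.tile_grid must be two integers >= 1, got {self.tile_grid}")
        return self


@dataclass
class RunConfig:
    """Composition of all stage configurations plus the run seed."""

    swarm: SwarmConfig = field(default_factory=SwarmConfig)
    superpixel: SuperpixelConfig = field(default_factory=SuperpixelConfig)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    clahe: ClaheConfig = field(default_factory=ClaheConfig)
    seed: int = 0
    match_radius: float = 8.0

    def validate(self) -> "RunConfig":
        self.swarm.validate()
        self.superpixel.validate()
        self.postprocess.validate()
        self.clahe.validate()
        if self.match_radius <= 0:
            raise ConfigError(f"match_radius must be > 0, got {self.match_radius}")
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["clahe"]["tile_grid"] = list(self.clahe.tile_grid)
        d["swarm"]["objectives"] = list(self.swarm.objectives)
        d["swarm"]["x_bounds"] = list(self.swarm.x_bounds)
        d["swarm"]["v_bounds"] = list(self.swarm.v_bounds)
        return d


_SECTIONS = {
    "swarm": SwarmConfig,
    "superpixel": SuperpixelConfig,
    "postprocess": PostprocessConfig,
    "clahe": ClaheConfig,
}
_TUPLE_FIELDS = {"tile_grid", "objectives", "x_bounds", "v_bounds"}


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in section '{section}': {sorted(unknown)}")
    kwargs = {k: tuple(v) if k in _TUPLE_FIELDS and v is not None else v for k, v in data.items()}
    return cls(**kwargs)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run configuration, or the full defaults when ``path``
    is None.  Unknown keys are rejected with the offending key named."""
    if path is None:
        return RunConfig().validate()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    known_top = set(_SECTIONS) | {"seed", "match_radius"}
    unknown = set(raw) - known_top
    if unknown:
        raise ConfigError(f"unknown top-level config key(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in raw:
            kwargs[name] = _build_section(cls, raw[name] or {}, name)
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    if "match_radius" in raw:
        kwargs["match_radius"] = float(raw["match_radius"])
    return RunConfig(**kwargs).validate()


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a configuration as YAML; ``load_config`` round-trips it."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
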