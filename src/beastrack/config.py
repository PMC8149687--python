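"""Run configuration: strict YAML loading into the dataclass configs.

Unknown keys are rejected with the offending field named, so typos in a
config file fail loudly instead of silently using a default.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .energy import EnergyConfig
from .synthetic import SceneConfig
from .tracking import DescentConfig

__all__ = ["RunConfig", "load_run_config", "ConfigError"]


class ConfigError(ValueError):
    pass


_SECTIONS = {
    "energy": EnergyConfig,
    "descent": DescentConfig,
    "scene": SceneConfig,
}
_TRACKING_KEYS = {"mode", "n_nodes", "nucleus_fraction", "seed"}


@dataclasses.dataclass
class RunConfig:
    energy: EnergyConfig
    descent: DescentConfig
    scene: SceneConfig | None = None
    mode: str = "one_layer"
    n_nodes: int = 32
    nucleus_fraction: float = 0.5
    seed: int = 0
    raw: dict = dataclasses.field(default_factory=dict)


def _build(cls, data: dict, section: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    for key in data:
        if key not in allowed:
            raise ConfigError(f"unknown key '{section}.{key}'")
    try:
        return cls(**{k: _coerce(v) for k, v in data.items()})
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{section}' section: {exc}") from exc


def _coerce(v):
    return tuple(v) if isinstance(v, list) and len(v) == 2 and all(
        isinstance(x, (int, float)) for x in v
    ) else v


def load_run_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML run config; ``None`` gives all defaults."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config root must be a mapping")
        data = loaded
    if overrides:
        data = {**data, **overrides}

    known = set(_SECTIONS) | {"tracking"}
    for key in data:
        if key not in known:
            raise ConfigError(f"unknown key '{key}'")

    sections = {}
    for name, cls in _SECTIONS.items():
        sections[name] = _build(cls, data.get(name, {}) or {}, name)

    tracking = data.get("tracking", {}) or {}
    for key in tracking:
        if key not in _TRACKING_KEYS:
            raise ConfigError(f"unknown key 'tracking.{key}'")
    mode = tracking.get("mode", "one_layer")
    if mode not in ("one_layer", "double"):
        raise ConfigError(f"invalid 'tracking.mode': {mode!r}")

    return RunConfig(
        energy=sections["energy"],
        descent=sections["descent"],
        scene=sections["scene"] if "scene" in data else None,
        mode=mode,
        n_nodes=int(tracking.get("n_nodes", 32)),
        nucleus_fraction=float(tracking.get("nucleus_fraction", 0.5)),
        seed=int(tracking.get("seed", 0)),
        raw=data,
    )
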