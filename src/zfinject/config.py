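"""Run configuration: defaults, YAML files, and CLI overrides.

Precedence is CLI flags > YAML file > built-in defaults.  Every run writes
its fully resolved configuration next to its outputs so results can be
audited and reproduced byte for byte.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .detection import DetectionConfig
from .workflow import PlateLayout, TimingModel


@dataclasses.dataclass
class RunConfig:
    """Everything a reproducible run needs: recognition parameters (the
    9 x 9 / 11-iteration dilation defaults among them), plate layout,
    timing model, pixel scale, and explicit seeds."""

    detection: DetectionConfig = dataclasses.field(default_factory=DetectionConfig)
    layout: PlateLayout = dataclasses.field(default_factory=lambda: PlateLayout(M=8, N=11))
    timing: TimingModel = dataclasses.field(default_factory=TimingModel)
    px_to_um: float = 10.0
    seed: int = 0
    failure_rate: float = 0.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["detection"]["radius_range"] = list(d["detection"]["radius_range"])
        d["layout"]["origin"] = list(d["layout"]["origin"])
        return d


def _apply(section_cls, base, overrides: dict):
    known = {f.name for f in dataclasses.fields(section_cls)}
    unknown = set(overrides) - known
    if unknown:
        raise ValueError(f"unknown {section_cls.__name__} keys: {sorted(unknown)}")
    merged = {**dataclasses.asdict(base), **overrides}
    if "radius_range" in merged and merged["radius_range"] is not None:
        merged["radius_range"] = tuple(merged["radius_range"])
    if "origin" in merged and merged["origin"] is not None:
        merged["origin"] = tuple(merged["origin"])
    return section_cls(**merged)


def load_config(path=None, **top_level) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides.

    ``top_level`` accepts the scalar fields of RunConfig plus nested dicts
    under ``detection`` / ``layout`` / ``timing``.
    """
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded:
            data.update(loaded)
    for key, val in top_level.items():
        if val is None:
            continue
        if key in ("detection", "layout", "timing"):
            data.setdefault(key, {}).update(val)
        else:
            data[key] = val

    cfg = RunConfig()
    cfg.detection = _apply(DetectionConfig, cfg.detection, data.pop("detection", {}))
    cfg.layout = _apply(PlateLayout, cfg.layout, data.pop("layout", {}))
    cfg.timing = _apply(TimingModel, cfg.timing, data.pop("timing", {}))
    for key in ("px_to_um", "seed", "failure_rate"):
        if key in data:
            setattr(cfg, key, data.pop(key))
    if data:
        raise ValueError(f"unknown config keys: {sorted(data)}")
    return cfg


def write_resolved_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
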