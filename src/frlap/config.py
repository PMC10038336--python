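"""Run configuration: one YAML file drives every pipeline stage.

Sections map onto the parameter dataclasses (``[helix]`` →
:class:`~frlap.helix.HelicalParams`, ``[placement]`` →
:class:`~frlap.helix.PlacementParams`, ``[medium]`` →
:class:`~frlap.photophysics.MediumParams`, ``[lineshapes]`` → per-class
:class:`~frlap.photophysics.LineshapeParams` overrides, ``[scheme]`` →
generator/fit settings, ``[seeds]`` → the seed registry).  Unknown keys are
rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .helix import HelicalParams, PlacementParams
from .photophysics import (DEFAULT_LINESHAPES, LineshapeParams, MediumParams)

__all__ = ["RunConfig", "load_config", "ConfigError"]

log = logging.getLogger("frlap")


class ConfigError(ValueError):
    pass


@dataclass
class SchemeConfig:
    n_protomers: int = 13
    lifetimes_ps: list = field(
        default_factory=lambda: [0.020, 0.517, 35.9, 889.0])
    irf_fwhm_ps: float = 0.096
    noise_pct: float = 1.0
    decay_ps: float = 889.0
    target_eet_ps: float = 0.517


@dataclass
class RunConfig:
    helix: HelicalParams = field(default_factory=HelicalParams)
    placement: PlacementParams = field(default_factory=PlacementParams)
    medium: MediumParams = field(default_factory=MediumParams)
    lineshapes: dict = field(
        default_factory=lambda: dict(DEFAULT_LINESHAPES))
    scheme: SchemeConfig = field(default_factory=SchemeConfig)
    seeds: dict = field(default_factory=lambda: {"ta": 1, "tcspc": 7,
                                                 "kmc": 2024})
    log_level: str = "INFO"


def _build(cls, section: dict, where: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise ConfigError(f"unknown keys in [{where}]: {sorted(unknown)}")
    return cls(**section)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load a YAML config; missing file/sections fall back to defaults."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if overrides:
        for sec, vals in overrides.items():
            raw.setdefault(sec, {}).update(vals)
    known = {"helix", "placement", "medium", "lineshapes", "scheme",
             "seeds", "log_level"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    cfg = RunConfig()
    if "helix" in raw:
        cfg.helix = _build(HelicalParams, raw["helix"], "helix")
    if "placement" in raw:
        cfg.placement = _build(PlacementParams, raw["placement"],
                               "placement")
    if "medium" in raw:
        cfg.medium = _build(MediumParams, raw["medium"], "medium")
    if "lineshapes" in raw:
        shapes = dict(DEFAULT_LINESHAPES)
        for cls_name, section in raw["lineshapes"].items():
            if cls_name not in ("alpha", "beta"):
                raise ConfigError(f"unknown lineshape class {cls_name!r}")
            base = dataclasses.asdict(DEFAULT_LINESHAPES[cls_name])
            valid = set(base)
            unknown = set(section) - valid
            if unknown:
                raise ConfigError(f"unknown keys in "
                                  f"[lineshapes.{cls_name}]: "
                                  f"{sorted(unknown)}")
            base.update(section)
            shapes[cls_name] = LineshapeParams(**base)
        cfg.lineshapes = shapes
    if "scheme" in raw:
        cfg.scheme = _build(SchemeConfig, raw["scheme"], "scheme")
    if "seeds" in raw:
        cfg.seeds = {**cfg.seeds, **raw["seeds"]}
    if "log_level" in raw:
        cfg.log_level = str(raw["log_level"])
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(),
                                      logging.INFO),
                        format="%(name)s %(levelname)s %(message)s")
    return cfg
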