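"""Run configuration: geometry, thresholds and model settings in one place.

A campaign is described by a small versioned YAML file; command-line flags
override file values so a field protocol can be pinned once and reused.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .inversion import InversionModel
from .protocol import PRESETS, ProtocolGeometry
from .segmentation import SegmentationParams

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    geometry: ProtocolGeometry = field(default_factory=ProtocolGeometry.field_protocol)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    model: InversionModel = field(default_factory=InversionModel)
    n_classes: int = 5
    seed: int = 0


def load_config(path: str | Path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML mapping.

    Recognised keys: ``geometry`` (either a preset name or a mapping with
    D/R/V), ``segmentation`` (brightness_cut, green_sat_min, ...),
    ``model`` (theta_deg, g_value), ``n_classes``, ``seed``.  Unknown keys
    raise, so typos fail loudly.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a YAML mapping")
    known = {"geometry", "segmentation", "model", "n_classes", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    cfg = RunConfig()
    if "geometry" in raw:
        g = raw["geometry"]
        if isinstance(g, str):
            if g not in PRESETS:
                raise ValueError(f"unknown geometry preset {g!r}")
            cfg = replace(cfg, geometry=PRESETS[g]())
        else:
            cfg = replace(cfg, geometry=ProtocolGeometry(**g))
    if "segmentation" in raw:
        s = dict(raw["segmentation"])
        if "cut_band" in s:
            s["cut_band"] = tuple(s["cut_band"])
        if "green_hue_band" in s:
            s["green_hue_band"] = tuple(s["green_hue_band"])
        cfg = replace(cfg, segmentation=SegmentationParams(**s))
    if "model" in raw:
        cfg = replace(cfg, model=InversionModel(**raw["model"]))
    if "n_classes" in raw:
        cfg = replace(cfg, n_classes=int(raw["n_classes"]))
    if "seed" in raw:
        cfg = replace(cfg, seed=int(raw["seed"]))
    return cfg
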