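"""YAML/JSON pipeline configuration.

A configuration file holds one block per operator (simulation, seed
detection, segmentation, fusion, tracking, evaluation) plus the
per-operator forward/backward FSMD thresholds.  Fuzzy-set definitions
serialise as ``{feature, a, b, c, d, term}`` mappings.  Every default is
echoed back into the emitted manifest, so parameters that were never set
explicitly remain visible in the run record.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .fuzzy import FuzzySet, TrapezoidParams
from .seeds import SeedDetectionConfig
from .segment import SegmentationConfig
from .simulate import AcquisitionConfig, DynamicsConfig
from .tables import OperatorThresholds
from .tracking import TrackingConfig

__all__ = [
    "PipelineConfig",
    "fuzzy_set_from_dict",
    "fuzzy_set_to_dict",
    "load_config",
    "dump_config",
]


def fuzzy_set_from_dict(d: dict) -> FuzzySet:
    return FuzzySet(
        name=d.get("term", "correct"),
        params=TrapezoidParams(float(d["a"]), float(d["b"]), float(d["c"]), float(d["d"])),
        feature=d["feature"],
    )


def fuzzy_set_to_dict(s: FuzzySet) -> dict:
    a, b, c, d = s.params.as_tuple()
    return {"feature": s.feature, "a": a, "b": b, "c": c, "d": d, "term": s.name}


@dataclass
class PipelineConfig:
    """All operator parameter blocks of one end-to-end run."""

    grid_shape: tuple[int, int, int] = (64, 256, 256)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (x, y, z)
    seed: int = 0
    dynamics: DynamicsConfig = field(default_factory=DynamicsConfig)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    seeds: SeedDetectionConfig = field(default_factory=SeedDetectionConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    match_radius: float | None = None  # default: r_min of the seed detector

    def resolved_match_radius(self) -> float:
        return self.match_radius if self.match_radius is not None else self.seeds.r_min


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        if isinstance(obj, FuzzySet):
            return fuzzy_set_to_dict(obj)
        if isinstance(obj, TrapezoidParams):
            return list(obj.as_tuple())
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if hasattr(obj, "value"):  # enums
        return obj.value
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def dump_config(config: PipelineConfig, path) -> None:
    """Write the full configuration (defaults included) as YAML."""
    plain = _to_plain(config)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(plain, fh, sort_keys=False)


def _thresholds(d: dict | None, default: OperatorThresholds) -> OperatorThresholds:
    if not d:
        return default
    return OperatorThresholds(
        alpha=float(d.get("alpha", default.alpha)),
        beta=float(d["beta"]) if "beta" in d else None,
    )


def load_config(path) -> PipelineConfig:
    """Load a YAML (or JSON) configuration file into a PipelineConfig."""
    path = Path(path)
    with open(path) as fh:
        if path.suffix.lower() == ".json":
            raw = json.load(fh)
        else:
            raw = yaml.safe_load(fh)
    raw = raw or {}
    cfg = PipelineConfig()
    if "grid_shape" in raw:
        cfg.grid_shape = tuple(raw["grid_shape"])
    if "spacing" in raw:
        cfg.spacing = tuple(raw["spacing"])
    cfg.seed = int(raw.get("seed", 0))
    if "dynamics" in raw:
        cfg.dynamics = DynamicsConfig(**raw["dynamics"])
    if "acquisition" in raw:
        acq = dict(raw["acquisition"])
        if "views" in acq:
            acq["views"] = tuple(acq["views"])
        if "psf_sigma" in acq:
            acq["psf_sigma"] = tuple(acq["psf_sigma"])
        cfg.acquisition = AcquisitionConfig(**acq)
    if "seeds" in raw:
        sd = dict(raw["seeds"])
        for key in ("window_mean_fuzzy", "max_intensity_fuzzy", "z_fuzzy"):
            if key in sd and sd[key] is not None:
                sd[key] = TrapezoidParams(*sd[key])
        if "radius_range" in sd:
            sd["radius_range"] = tuple(sd["radius_range"])
        if "sigma_factors" in sd:
            sd["sigma_factors"] = tuple(sd["sigma_factors"])
        cfg.seeds = SeedDetectionConfig(**sd)
    if "segmentation" in raw:
        sg = dict(raw["segmentation"])
        thr = _thresholds(sg.pop("thresholds", None), OperatorThresholds(0.1, 0.5))
        sets = [fuzzy_set_from_dict(s) for s in sg.pop("sets", [])]
        cfg.segmentation = SegmentationConfig(thresholds=thr, sets=sets, **sg)
    if "tracking" in raw:
        tr = dict(raw["tracking"])
        thr = _thresholds(tr.pop("thresholds", None), OperatorThresholds(0.0, 0.9))
        if "spacing" in tr:
            tr["spacing"] = tuple(tr["spacing"])
        cfg.tracking = TrackingConfig(thresholds=thr, **tr)
    if raw.get("match_radius") is not None:
        cfg.match_radius = float(raw["match_radius"])
    return cfg
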