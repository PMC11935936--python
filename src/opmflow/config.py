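"""Structured run configuration (YAML) with strict key validation and a
stable global-seed → per-stage seed derivation."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .geometry import ChannelGeometry
from .flow import AcousticConfig, FlowConfig
from .imaging import MovieConfig, OpticsConfig
from .segment import SegParams
from .tracking import DetectParams


@dataclass(frozen=True)
class SceneSection:
    n_cells: int = 200
    size_mean: float = 10.0   # um diameter
    size_sd: float = 1.0
    phase_fractions: dict = field(default_factory=lambda: {
        "interphase": 0.960, "prophase": 0.027, "metaphase": 0.008,
        "anaphase": 0.002, "telophase": 0.003})
    length_l: float = 1000.0  # simulated channel-segment length, um


@dataclass(frozen=True)
class AcquireSection:
    n_frames: int = 100
    channels: tuple = ("cyto", "dna", "mitotic_marker")


@dataclass(frozen=True)
class DeskewSection:
    interpolation: str = "linear"
    velocity: float | None = None   # um/s; None → stack metadata


@dataclass(frozen=True)
class TrackingSection:
    n_frames: int = 120
    max_displacement: float = 20.0  # um
    memory: int = 1


@dataclass(frozen=True)
class AnalysisSection:
    marker_threshold: float = 1000.0
    ratio_threshold: float = 0.6
    pair_distance: float | None = None
    region_threshold: str = "half_max"
    min_region_volume: float = 2.0


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    scene: SceneSection = SceneSection()
    flow: FlowConfig = FlowConfig()
    acoustics: AcousticConfig = AcousticConfig()
    optics: OpticsConfig = OpticsConfig()
    movie: MovieConfig = MovieConfig()
    acquire: AcquireSection = AcquireSection()
    deskew: DeskewSection = DeskewSection()
    segmentation: SegParams = SegParams()
    tracking: TrackingSection = TrackingSection()
    detect: DetectParams = DetectParams()
    analysis: AnalysisSection = AnalysisSection()

    # -- seed fan-out -------------------------------------------------------

    _STAGES = ("scene", "focusing", "acquire", "movie", "noise", "analysis")

    def stage_seed(self, stage: str) -> int:
        """Stable child seed (< 2**31) for one pipeline stage."""
        if stage not in self._STAGES:
            raise KeyError(f"unknown stage {stage!r}")
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "little") % (2 ** 31)

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: conv(getattr(obj, f.name)) for f in fields(obj)}
            if isinstance(obj, (tuple, list)):
                return [conv(x) for x in obj]
            if isinstance(obj, dict):
                return {k: conv(v) for k, v in obj.items()}
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj
        return conv(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d or {})

        def build(klass, sub):
            if sub is None:
                return klass()
            names = {f.name for f in fields(klass)}
            unknown = set(sub) - names
            if unknown:
                raise ValueError(f"unknown keys for {klass.__name__}: {sorted(unknown)}")
            return klass(**dict(sub))

        flow_sub = dict(d.pop("flow", {}) or {})
        geom_sub = flow_sub.pop("geometry", None)
        geometry = build(ChannelGeometry, geom_sub)
        flow = FlowConfig(geometry=geometry, **flow_sub)

        kwargs = {"flow": flow}
        section_types = {
            "scene": SceneSection, "acoustics": AcousticConfig,
            "optics": OpticsConfig, "movie": MovieConfig,
            "acquire": AcquireSection, "deskew": DeskewSection,
            "segmentation": SegParams, "tracking": TrackingSection,
            "detect": DetectParams, "analysis": AnalysisSection,
        }
        for key, klass in section_types.items():
            if key in d:
                sub = d.pop(key)
                if klass is AcquireSection and sub and "channels" in sub:
                    sub = dict(sub, channels=tuple(sub["channels"]))
                kwargs[key] = build(klass, sub)
        if "seed" in d:
            kwargs["seed"] = int(d.pop("seed"))
        if d:
            raise ValueError(f"unknown top-level config keys: {sorted(d)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, text_or_path: str | Path) -> "RunConfig":
        text = str(text_or_path)
        if isinstance(text_or_path, Path) or ("\n" not in text and text.endswith((".yaml", ".yml"))):
            text = Path(text_or_path).read_text()
        return cls.from_dict(yaml.safe_load(text) or {})
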