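"""Run configuration: magnification table, per-stage parameters, validation.

A run is described by a single YAML mapping; unknown keys are rejected so a
typo never silently falls back to a default. Every stochastic operation takes
its seed from here, which makes a run directory reproducible from its config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Dict, Optional, Tuple

import yaml

__all__ = [
    "MAG_PIXELS_PER_UM",
    "MAG_LADDER",
    "FOV_PX",
    "ConfigError",
    "RunConfig",
    "load_config",
]

# Declared pixel sizes per magnification (pixels per micrometre) for the
# two LM lenses and the EM magnification steps; all config-overridable.
MAG_PIXELS_PER_UM: Dict[str, float] = {
    "20x": 2.96,
    "100x": 15.38,
    "4kx": 43.03,
    "12kx": 129.08,
    "30kx": 322.69,
}

# The refinement ladder: registration measured at one rung feeds the
# stage targets of all higher rungs.
MAG_LADDER: Tuple[str, ...] = ("20x", "100x", "4kx", "12kx", "30kx")

# Simulated camera frame size (pixels) per magnification. The 20x frame is
# kept below one section pitch so a frame never contains the tracked
# structure of a neighbouring section.
FOV_PX: Dict[str, int] = {
    "20x": 160,
    "100x": 384,
    "4kx": 384,
    "12kx": 384,
    "30kx": 384,
}


class ConfigError(ValueError):
    """Invalid or unknown configuration content (exit code 2 in the CLI)."""


@dataclass
class RunConfig:
    """Validated parameters for an end-to-end run.

    Defaults reproduce the synthetic proof-of-concept layout; any field can
    be overridden from YAML or CLI flags.
    """

    # frames and magnifications
    pixels_per_um: Dict[str, float] = field(default_factory=lambda: dict(MAG_PIXELS_PER_UM))
    fov_px: Dict[str, int] = field(default_factory=lambda: dict(FOV_PX))
    ladder: Tuple[str, ...] = ("20x", "100x")
    axis_signs: Tuple[int, int] = (1, 1)
    settle_s: float = 2.0

    # preprocessing (see imageproc.preprocess_overview)
    stretch_percentiles: Tuple[float, float] = (0.5, 99.5)
    sigma_blur_px: float = 2.0
    min_area_px: int = 100
    edge_soft_px: float = 3.0

    # detection (see detection.fit_active_contour / detect_all_sections)
    lambda_shape: float = 0.3
    search_radius_px: int = 10
    reject_fraction: float = 0.4
    pyramid_levels: Tuple[int, ...] = (4, 2, 1)

    # registration / refinement
    registration_mode: str = "translation"
    upsample_factor: int = 10

    # simulation
    stage_jitter_um: float = 0.0
    stitch_tiles: bool = False
    seed: int = 0

    # paths (None when driven programmatically)
    scene_path: Optional[str] = None
    out_dir: Optional[str] = None

    def __post_init__(self):
        if self.registration_mode not in ("translation", "rigid"):
            raise ConfigError(f"registration_mode must be translation|rigid, got {self.registration_mode!r}")
        for m in self.ladder:
            if m not in self.pixels_per_um:
                raise ConfigError(f"magnification {m!r} has no declared pixel size")
        if any(v <= 0 for v in self.pixels_per_um.values()):
            raise ConfigError("pixel sizes must be positive")
        if tuple(self.axis_signs) not in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
            raise ConfigError(f"axis_signs must be (+/-1, +/-1), got {self.axis_signs}")
        if self.settle_s < 0:
            raise ConfigError("settle_s must be non-negative")

    @classmethod
    def from_dict(cls, d: Dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        kwargs = dict(d)
        for k in ("ladder", "axis_signs", "stretch_percentiles", "pyramid_levels"):
            if k in kwargs and isinstance(kwargs[k], list):
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)

    def to_dict(self) -> Dict[str, Any]:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def content_hash(self) -> str:
        """Stable hash recorded in every artifact for provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    return RunConfig.from_dict(raw)
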