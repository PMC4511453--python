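"""Trial configuration: acquisition calibration and detection thresholds.

All geometry in the package is expressed in image pixel coordinates
(0-based, origin top-left, x rightward along the walkway, y downward)
until the coordination stage transforms footprints into the body frame.
The frame rate and the spatial calibration are never inferred from the
frames; they always come from the configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml


def _triple(v) -> tuple[float, float, float]:
    if isinstance(v, (int, float)):
        return (float(v),) * 3
    t = tuple(float(x) for x in v)
    if len(t) == 1:
        return (t[0],) * 3
    if len(t) != 3:
        raise ValueError(f"expected a scalar or 3 channel values, got {v!r}")
    return t


@dataclass
class TrialConfig:
    """Calibration and thresholds for one fTIR walking trial.

    Channel thresholds are inclusive [min, max] ranges per channel
    (grayscale input uses the same range on its single channel).  A pixel
    within ``bg_tolerance`` of its per-pixel background median is always
    background; otherwise the footprint rule takes precedence over the
    body rule.
    """

    frame_rate_hz: float = 250.0
    px_per_cm: float = 10.0

    # segmentation
    bg_tolerance: tuple[float, float, float] = (12.0, 12.0, 12.0)
    body_rgb_min: tuple[float, float, float] = (60.0, 60.0, 60.0)
    body_rgb_max: tuple[float, float, float] = (160.0, 160.0, 160.0)
    footprint_rgb_min: tuple[float, float, float] = (170.0, 170.0, 170.0)
    footprint_rgb_max: tuple[float, float, float] = (255.0, 255.0, 255.0)
    tail_thickness_frac: float = 0.25   # of the maximum body cross-section width
    min_tail_frac: float = 0.10         # min tail run, fraction of body axis extent
    head_distance_frac: float = 0.25    # of body length (nose to tail base)
    min_blob_area: int = 4              # px
    min_body_area: int = 200            # px

    # tracking
    max_link_dist_px: float = 20.0
    max_stance_drift_px: float = 5.0    # per frame; stance feet are anchored
    max_gap_frames: int = 2
    min_stance_frames: int = 3
    fore_hind_split: float = 0.0        # body-length units, anterior of body center
    leg_dead_zone: float = 0.02         # body-length units around the split

    # kinematics / coordination
    speed_smooth_win: int = 5           # frames
    linearity_smooth_win: int = 15      # frames

    def __post_init__(self) -> None:
        for name in ("bg_tolerance", "body_rgb_min", "body_rgb_max",
                     "footprint_rgb_min", "footprint_rgb_max"):
            setattr(self, name, _triple(getattr(self, name)))
        for name in ("body_rgb_min", "body_rgb_max",
                     "footprint_rgb_min", "footprint_rgb_max"):
            for v in getattr(self, name):
                if not 0.0 <= v <= 255.0:
                    raise ValueError(f"{name} value {v} outside [0, 255]")
        if any(t < 0 for t in self.bg_tolerance):
            raise ValueError("bg_tolerance must be >= 0")
        if self.frame_rate_hz <= 0 or self.px_per_cm <= 0:
            raise ValueError("frame_rate_hz and px_per_cm must be positive")

    # -- derived helpers -------------------------------------------------
    @property
    def min_stance_s(self) -> float:
        return self.min_stance_frames / self.frame_rate_hz

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrialConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "TrialConfig":
        """Read a config file; calibration keys must be stated, not defaulted."""
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        require_keys(d)
        return cls(**d)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


REQUIRED_KEYS: Sequence[str] = ("frame_rate_hz", "px_per_cm")


def require_keys(d: dict) -> None:
    """Raise with the offending key name if a mandatory key is absent."""
    for key in REQUIRED_KEYS:
        if key not in d:
            raise KeyError(f"missing required config key: {key}")
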