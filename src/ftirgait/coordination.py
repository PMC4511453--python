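"""Inter-leg coordination and body-frame footprint geometry.

Stance traces are footprint trajectories expressed in the body frame
(origin at the body center, longitudinal axis toward the nose, normalized
to body length).  A foot is anchored to the floor during stance, so its
trace runs from the anterior extreme position (AEP, touchdown) to the
posterior extreme position (PEP, liftoff) as the body advances over it.
From the traces and the stance schedule this module derives footprint
clustering, stance linearity, the seven leg-combination indexes,
contralateral phases, tail kinematics and footprint pressure series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import TrialConfig
from .segmentation import BodyPose
from .tracking import LEGS, LegId, StanceEvent, StepCycle

# ---------------------------------------------------------------------------
# body-frame transform
# ---------------------------------------------------------------------------


@dataclass
class BodyFramePoint:
    """Footprint position in body-length units.

    longitudinal: + anterior of the body center (toward the nose).
    lateral: + toward the animal's left.  The walkway is imaged from below,
    so with the image y-axis pointing down the animal's left side lies at
    +90 deg from its heading in image coordinates.
    """

    longitudinal: float
    lateral: float


def to_body_frame(point_px: tuple[float, float], pose: BodyPose,
                  px_per_cm: float) -> BodyFramePoint:
    """Pixel point -> body frame: translate, rotate, normalize to body length."""
    bl_px = pose.body_length * px_per_cm
    if bl_px <= 0:
        raise ValueError("pose has non-positive body length")
    dx = point_px[0] - pose.body_center[0]
    dy = point_px[1] - pose.body_center[1]
    c, s = np.cos(pose.body_orientation), np.sin(pose.body_orientation)
    longitudinal = (dx * c + dy * s) / bl_px
    lateral = (-dx * s + dy * c) / bl_px
    return BodyFramePoint(float(longitudinal), float(lateral))


def from_body_frame(point: BodyFramePoint, pose: BodyPose,
                    px_per_cm: float) -> tuple[float, float]:
    """Inverse of :func:`to_body_frame`."""
    bl_px = pose.body_length * px_per_cm
    c, s = np.cos(pose.body_orientation), np.sin(pose.body_orientation)
    lx = point.longitudinal * bl_px
    ly = point.lateral * bl_px
    return (pose.body_center[0] + lx * c - ly * s,
            pose.body_center[1] + lx * s + ly * c)


# ---------------------------------------------------------------------------
# stance traces
# ---------------------------------------------------------------------------


@dataclass
class StanceTrace:
    leg: Optional[LegId]
    frames: np.ndarray                # frame numbers, one per stance frame
    points: np.ndarray                # (n, 2): longitudinal, lateral
    flagged: bool = False             # too few tracked poses; exclude

    @property
    def aep(self) -> BodyFramePoint:
        return BodyFramePoint(*self.points[0])

    @property
    def pep(self) -> BodyFramePoint:
        return BodyFramePoint(*self.points[-1])


def _interpolated_pose_table(poses: Mapping[int, BodyPose],
                             frames: np.ndarray) -> tuple[np.ndarray, ...]:
    """Per-frame (cx, cy, theta, body_length) with linear interpolation.

    Orientation is unwrapped before interpolation so a heading near +/-pi
    does not interpolate through zero.
    """
    tracked = np.array(sorted(poses))
    cx = np.array([poses[int(f)].body_center[0] for f in tracked])
    cy = np.array([poses[int(f)].body_center[1] for f in tracked])
    th = np.unwrap(np.array([poses[int(f)].body_orientation for f in tracked]))
    bl = np.array([poses[int(f)].body_length for f in tracked])
    return (np.interp(frames, tracked, cx), np.interp(frames, tracked, cy),
            np.interp(frames, tracked, th), np.interp(frames, tracked, bl))


def build_stance_trace(event: StanceEvent, poses: Mapping[int, BodyPose],
                       cfg: TrialConfig) -> StanceTrace:
    """Body-frame trajectory of one stance event's per-frame centroids.

    Requires a tracked pose for at least 80% of the event's frames; below
    that the trace is flagged and callers exclude it from aggregates.
    Missing poses inside the event are linearly interpolated.
    """
    frames = np.arange(event.onset_frame, event.offset_frame + 1)
    n_tracked = sum(1 for f in frames if int(f) in poses)
    flagged = n_tracked < 0.8 * len(frames)
    cx, cy, th, bl = _interpolated_pose_table(poses, frames)
    pts = np.empty((len(frames), 2))
    for i in range(len(frames)):
        dx = event.centroids[i, 0] - cx[i]
        dy = event.centroids[i, 1] - cy[i]
        c, s = np.cos(th[i]), np.sin(th[i])
        bl_px = bl[i] * cfg.px_per_cm
        pts[i, 0] = (dx * c + dy * s) / bl_px
        pts[i, 1] = (-dx * s + dy * c) / bl_px
    return StanceTrace(leg=event.leg, frames=frames, points=pts,
                       flagged=flagged)


def _shrunk_moving_average(arr: np.ndarray, win: int) -> np.ndarray:
    """Centered moving average per column, symmetrically shrunk at the ends."""
    n = arr.shape[0]
    out = np.empty_like(arr, dtype=float)
    half = win // 2
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = arr[i - h:i + h + 1].mean(axis=0)
    return out


def stance_linearity_index(trace: StanceTrace,
                           smooth_win: int = 15) -> Optional[float]:
    """Mean deviation of a stance trace from its smoothed version.

    A wobble-free stance trace is a straight body-frame line; jitter of the
    body axis shows up as deviation from the smoothed path.  Undefined
    (None) for traces shorter than the smoothing window.
    """
    if trace.points.shape[0] < smooth_win:
        return None
    smooth = _shrunk_moving_average(trace.points, smooth_win)
    d = np.hypot(*(trace.points - smooth).T)
    return float(d.mean())


def trial_stance_linearity(traces: Iterable[StanceTrace],
                           smooth_win: int = 15) -> Optional[float]:
    """Flat mean of the linearity index over all usable traces of all legs."""
    vals = [stance_linearity_index(t, smooth_win)
            for t in traces if not t.flagged]
    vals = [v for v in vals if v is not None]
    return float(np.mean(vals)) if vals else None


def body_linearity_index(poses: Mapping[int, BodyPose], cfg: TrialConfig,
                         smooth_win: int = 15) -> Optional[float]:
    """Same deviation-from-smoothed-path measure on the body-center path, mm."""
    frames = np.array(sorted(poses))
    if len(frames) < smooth_win:
        return None
    path = np.array([poses[int(f)].body_center for f in frames])
    smooth = _shrunk_moving_average(path, smooth_win)
    d = np.hypot(*(path - smooth).T)
    return float(d.mean() * 10.0 / cfg.px_per_cm)


# ---------------------------------------------------------------------------
# footprint clustering
# ---------------------------------------------------------------------------


def footprint_clustering(traces: Sequence[StanceTrace],
                         endpoint: str) -> Optional[float]:
    """Standard distance of AEP (or PEP) positions across steps, per video.

    Per leg with at least two steps: sqrt(var(longitudinal) + var(lateral))
    with population variances; the trial value is the mean over qualifying
    legs.  None when no leg has two steps.
    """
    if endpoint not in ("AEP", "PEP"):
        raise ValueError("endpoint must be 'AEP' or 'PEP'")
    per_leg: dict[LegId, list[tuple[float, float]]] = {}
    for t in traces:
        if t.flagged or t.leg is None:
            continue
        p = t.aep if endpoint == "AEP" else t.pep
        per_leg.setdefault(t.leg, []).append((p.longitudinal, p.lateral))
    vals = []
    for leg, pts in per_leg.items():
        if len(pts) < 2:
            continue
        arr = np.asarray(pts)
        vals.append(float(np.sqrt(arr[:, 0].var() + arr[:, 1].var())))
    return float(np.mean(vals)) if vals else None


# ---------------------------------------------------------------------------
# leg-combination categories
# ---------------------------------------------------------------------------

CATEGORIES = ("no_swing", "single", "diagonal", "lateral", "front_or_hind",
              "three_leg", "all_legs")

_PAIR_CATEGORY = {
    frozenset({LegId.LF, LegId.RH}): "diagonal",
    frozenset({LegId.RF, LegId.LH}): "diagonal",
    frozenset({LegId.LF, LegId.LH}): "lateral",
    frozenset({LegId.RF, LegId.RH}): "lateral",
    frozenset({LegId.LF, LegId.RF}): "front_or_hind",
    frozenset({LegId.LH, LegId.RH}): "front_or_hind",
}


@dataclass
class CombinationIndexes:
    fractions: dict[str, float]
    n_frames: int

    def __getitem__(self, cat: str) -> float:
        return self.fractions[cat]


def frame_combination(stance_flags: Mapping[LegId, bool]) -> str:
    """Category of one frame's swing combination (total over all 16 cases)."""
    swinging = frozenset(leg for leg in LEGS if not stance_flags[leg])
    n = len(swinging)
    if n == 0:
        return "no_swing"
    if n == 1:
        return "single"
    if n == 3:
        return "three_leg"
    if n == 4:
        return "all_legs"
    return _PAIR_CATEGORY[swinging]


def stance_flags_by_frame(events: Sequence[StanceEvent],
                          frame_range: tuple[int, int]) -> dict[int, dict[LegId, bool]]:
    """Per-frame stance flags from (gap-filled) stance-event intervals."""
    first, last = frame_range
    flags = {f: {leg: False for leg in LEGS} for f in range(first, last + 1)}
    for ev in events:
        if ev.leg is None:
            continue
        for f in range(max(ev.onset_frame, first), min(ev.offset_frame, last) + 1):
            flags[f][ev.leg] = True
    return flags


def combination_indexes(categories: Sequence[str]) -> CombinationIndexes:
    """Fraction of classified frames in each of the seven categories."""
    cats = [c for c in categories if c in CATEGORIES]
    if not cats:
        raise ValueError("no classified frames")
    n = len(cats)
    fr = {c: 0 for c in CATEGORIES}
    for c in cats:
        fr[c] += 1
    return CombinationIndexes({c: fr[c] / n for c in CATEGORIES}, n)


# ---------------------------------------------------------------------------
# contralateral phase
# ---------------------------------------------------------------------------


@dataclass
class PhaseEstimate:
    pair: str                   # 'fore' or 'hind'
    mean_phase: float           # fraction of cycle in [0, 1)
    dispersion: float           # circular SD, cycle fractions
    n: int


def circular_mean_phase(phases: Sequence[float]) -> tuple[float, float]:
    """Circular mean and circular SD of cycle fractions in [0, 1)."""
    ang = 2.0 * np.pi * np.asarray(phases, dtype=float)
    C, S = np.cos(ang).mean(), np.sin(ang).mean()
    mean = float(np.arctan2(S, C) / (2.0 * np.pi)) % 1.0
    R = float(np.hypot(C, S))
    sd = float(np.sqrt(max(0.0, -2.0 * np.log(max(R, 1e-300)))) / (2.0 * np.pi))
    return mean, sd


def contralateral_phase(ref_cycles: Sequence[StepCycle],
                        partner_onsets: Sequence[int],
                        pair: str) -> Optional[PhaseEstimate]:
    """Phase of the partner leg's touchdowns within the reference leg's cycles.

    For each reference cycle [t_i, t_{i+1}) the partner onset falling inside
    it yields phase (t_p - t_i)/(t_{i+1} - t_i); cycles without a partner
    onset are skipped.  Anti-phase stepping gives a mean near 0.5.  Circular
    statistics handle phases near the 0/1 wrap correctly.
    """
    onsets = np.sort(np.asarray(partner_onsets, dtype=float))
    phases = []
    for cyc in ref_cycles:
        t0, t1 = cyc.stance_onset, cyc.next_stance_onset
        inside = onsets[(onsets >= t0) & (onsets < t1)]
        if inside.size:
            phases.append(float((inside[0] - t0) / (t1 - t0)))
    if len(phases) < 2:
        return None
    mean, sd = circular_mean_phase(phases)
    return PhaseEstimate(pair=pair, mean_phase=mean, dispersion=sd,
                         n=len(phases))


# ---------------------------------------------------------------------------
# tail metrics
# ---------------------------------------------------------------------------


def tail_metrics(poses: Mapping[int, BodyPose],
                 cfg: TrialConfig) -> pd.DataFrame:
    """Per-frame tail statistics relative to the body axis.

    Columns: the three tail-segment orientations minus the body orientation
    (proximal/middle/distal, radians, wrapped), proximal and distal
    orientations minus the middle one, and the perpendicular velocity of the
    middle tail point (its frame-to-frame displacement projected onto the
    body-frame lateral axis, cm/s).  Frames without a tracked tail yield NaN.
    """
    frames = sorted(poses)
    rows = []
    prev_mid: Optional[tuple[int, tuple[float, float]]] = None
    for f in frames:
        p = poses[f]
        row = {"frame": f, "time_s": f / cfg.frame_rate_hz}
        if len(p.tail_orientations) == 3 and len(p.tail_points) == 3:
            prox, mid, dist = p.tail_orientations
            wrap = lambda a: float((a + np.pi) % (2 * np.pi) - np.pi)
            row["proximal_vs_body"] = wrap(prox - p.body_orientation)
            row["middle_vs_body"] = wrap(mid - p.body_orientation)
            row["distal_vs_body"] = wrap(dist - p.body_orientation)
            row["proximal_vs_middle"] = wrap(prox - mid)
            row["distal_vs_middle"] = wrap(dist - mid)
            mid_pt = p.tail_points[1]
            if prev_mid is not None and f - prev_mid[0] == 1:
                dx = mid_pt[0] - prev_mid[1][0]
                dy = mid_pt[1] - prev_mid[1][1]
                c, s = np.cos(p.body_orientation), np.sin(p.body_orientation)
                lat_px = -dx * s + dy * c
                row["tail_perp_velocity_cm_s"] = (
                    lat_px * cfg.frame_rate_hz / cfg.px_per_cm)
            else:
                row["tail_perp_velocity_cm_s"] = np.nan
            prev_mid = (f, mid_pt)
        else:
            for k in ("proximal_vs_body", "middle_vs_body", "distal_vs_body",
                      "proximal_vs_middle", "distal_vs_middle",
                      "tail_perp_velocity_cm_s"):
                row[k] = np.nan
            prev_mid = None
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# footprint pressure
# ---------------------------------------------------------------------------


def pressure_series(event: StanceEvent, cfg: TrialConfig) -> pd.DataFrame:
    """Per-frame footprint area (cm^2), summed intensity and intensity/area.

    The fTIR signal intensity scales with the applied pressure, so
    intensity/area is a relative pressure readout (no absolute calibration).
    Gap-filled frames with zero area yield NaN pressure.
    """
    if event.n_frames == 0:
        raise ValueError("empty stance event")
    frames = np.arange(event.onset_frame, event.offset_frame + 1)
    area_cm2 = event.areas / cfg.px_per_cm ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        pressure = np.where(event.areas > 0,
                            event.brightness / np.maximum(event.areas, 1),
                            np.nan)
    return pd.DataFrame({
        "frame": frames,
        "time_s": frames / cfg.frame_rate_hz,
        "area_cm2": area_cm2,
        "intensity": event.brightness,
        "pressure": pressure,
    })
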