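"""Footprint tracking: blobs -> stance events -> leg identities -> step cycles.

A stance footprint is anchored to the floor, so frame-to-frame linking is a
greedy nearest-centroid match with a small search radius; short dropouts
(fTIR flicker) are bridged by linear interpolation.  Leg identity is read
off the footprint's position in the body frame at stance onset: side from
the lateral coordinate, fore/hind from the longitudinal coordinate relative
to the body center.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np

from .config import TrialConfig
from .segmentation import BodyPose, FootprintBlob


class LegId(str, Enum):
    LF = "LF"   # left fore
    LH = "LH"   # left hind
    RF = "RF"   # right fore
    RH = "RH"   # right hind


LEGS: tuple[LegId, ...] = (LegId.LF, LegId.LH, LegId.RF, LegId.RH)


@dataclass
class StanceEvent:
    """One contiguous ground-contact episode of one footprint.

    ``onset_frame``/``offset_frame`` are inclusive; gap frames bridged by the
    linker carry interpolated centroids and zero area/brightness.
    """

    onset_frame: int
    offset_frame: int
    centroids: np.ndarray             # (n, 2) per-frame (x, y) px
    areas: np.ndarray                 # (n,) px counts (0 on gap frames)
    brightness: np.ndarray            # (n,) sums (0 on gap frames)
    leg: Optional[LegId] = None
    flags: list[str] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.offset_frame - self.onset_frame + 1

    @property
    def mean_centroid(self) -> tuple[float, float]:
        return (float(self.centroids[:, 0].mean()),
                float(self.centroids[:, 1].mean()))

    def duration_s(self, frame_rate: float) -> float:
        return self.n_frames / frame_rate


@dataclass
class StepCycle:
    """One stride: a stance plus the swing up to the next same-leg stance."""

    leg: LegId
    stance_onset: int
    stance_offset: int
    next_stance_onset: int
    stance_time: float                # s
    swing_time: float                 # s
    period: float                     # s
    step_length: float                # mm
    degenerate: bool = False          # no swing detected


# ---------------------------------------------------------------------------
# blob linking
# ---------------------------------------------------------------------------


class _Track:
    __slots__ = ("frames", "centroids", "areas", "brightness", "open")

    def __init__(self) -> None:
        self.frames: list[int] = []
        self.centroids: list[tuple[float, float]] = []
        self.areas: list[int] = []
        self.brightness: list[float] = []
        self.open = True


def link_blobs(blobs_by_frame: Mapping[int, Sequence[FootprintBlob]],
               cfg: TrialConfig) -> list[StanceEvent]:
    """Greedy nearest-centroid linking of per-frame blobs into stance events.

    Tracks tolerate up to ``max_gap_frames`` consecutive missing frames;
    bridged frames get linearly interpolated centroids and count as contact.
    Tracks shorter than ``min_stance_frames`` are discarded.  When two blobs
    in one frame both fall within range of a track, the closer one extends
    it and the other seeds a new track.

    A stance footprint is anchored to the floor, so a link must also respect
    ``max_stance_drift_px`` per elapsed frame; this keeps a hind paw landing
    next to a just-lifted forepaw (the overlap typical of walking mice) from
    being welded onto the forepaw's track.
    """
    frames = sorted(blobs_by_frame)
    tracks: list[_Track] = []
    for f in frames:
        blobs = list(blobs_by_frame[f])
        # close stale tracks
        for t in tracks:
            if t.open and f - t.frames[-1] > cfg.max_gap_frames + 1:
                t.open = False
        candidates = [t for t in tracks if t.open]
        # all (distance, track, blob) pairs within range, greedily matched
        pairs = []
        for ti, t in enumerate(candidates):
            tx, ty = t.centroids[-1]
            elapsed = f - t.frames[-1]
            limit = min(cfg.max_link_dist_px,
                        cfg.max_stance_drift_px * elapsed)
            for bi, b in enumerate(blobs):
                d = float(np.hypot(b.centroid[0] - tx, b.centroid[1] - ty))
                if d <= limit:
                    pairs.append((d, ti, bi))
        pairs.sort(key=lambda p: p[0])
        used_t: set[int] = set()
        used_b: set[int] = set()
        for d, ti, bi in pairs:
            if ti in used_t or bi in used_b:
                continue
            used_t.add(ti)
            used_b.add(bi)
            t, b = candidates[ti], blobs[bi]
            t.frames.append(f)
            t.centroids.append(b.centroid)
            t.areas.append(b.area_px)
            t.brightness.append(b.brightness_sum)
        for bi, b in enumerate(blobs):
            if bi in used_b:
                continue
            t = _Track()
            t.frames.append(f)
            t.centroids.append(b.centroid)
            t.areas.append(b.area_px)
            t.brightness.append(b.brightness_sum)
            tracks.append(t)

    events: list[StanceEvent] = []
    for t in tracks:
        n = t.frames[-1] - t.frames[0] + 1
        if n < cfg.min_stance_frames:
            continue
        cents = np.full((n, 2), np.nan)
        areas = np.zeros(n, dtype=int)
        bright = np.zeros(n)
        for fr, c, a, b in zip(t.frames, t.centroids, t.areas, t.brightness):
            i = fr - t.frames[0]
            cents[i] = c
            areas[i] = a
            bright[i] = b
        # bridge gap frames by linear interpolation of the centroid series
        for axis in range(2):
            col = cents[:, axis]
            missing = np.isnan(col)
            if missing.any():
                idx = np.arange(n)
                col[missing] = np.interp(idx[missing], idx[~missing],
                                         col[~missing])
        events.append(StanceEvent(
            onset_frame=t.frames[0],
            offset_frame=t.frames[-1],
            centroids=cents,
            areas=areas,
            brightness=bright,
        ))
    events.sort(key=lambda e: (e.onset_frame, e.mean_centroid[0]))
    return events


# ---------------------------------------------------------------------------
# leg identity
# ---------------------------------------------------------------------------


def assign_leg_identity(events: Sequence[StanceEvent],
                        poses: Mapping[int, BodyPose],
                        cfg: TrialConfig) -> list[StanceEvent]:
    """Label each stance event with a leg identity from its body-frame position.

    The event's mean centroid is transformed into the body frame of the pose
    at stance onset (nearest tracked frame if the onset itself is untracked):
    a positive lateral coordinate means the animal's left side; longitudinal
    coordinates at or anterior of ``fore_hind_split`` mean a foreleg.  Events
    inside the dead zone around the split inherit the label of the nearest
    preceding event on a candidate leg, by spatial continuity; with no such
    event they are flagged ambiguous.
    """
    from .coordination import to_body_frame

    if not poses:
        raise ValueError("no poses available for leg assignment")
    pose_frames = np.array(sorted(poses))
    out: list[StanceEvent] = []
    labeled: dict[LegId, list[StanceEvent]] = {leg: [] for leg in LEGS}
    for ev in sorted(events, key=lambda e: e.onset_frame):
        j = int(np.argmin(np.abs(pose_frames - ev.onset_frame)))
        pose = poses[int(pose_frames[j])]
        pt = to_body_frame(ev.mean_centroid, pose, cfg.px_per_cm)
        side_left = pt.lateral > 0
        long = pt.longitudinal
        if abs(long - cfg.fore_hind_split) <= cfg.leg_dead_zone:
            candidates = ([LegId.LF, LegId.LH] if side_left
                          else [LegId.RF, LegId.RH])
            prev_best = None
            best_d = np.inf
            for leg in candidates:
                if labeled[leg]:
                    p = labeled[leg][-1]
                    d = np.hypot(p.mean_centroid[0] - ev.mean_centroid[0],
                                 p.mean_centroid[1] - ev.mean_centroid[1])
                    if d < best_d:
                        best_d, prev_best = d, leg
            if prev_best is None:
                ev.flags.append("ambiguous_leg")
                ev.leg = candidates[0]
            else:
                ev.leg = prev_best
        else:
            fore = long >= cfg.fore_hind_split
            ev.leg = {(True, True): LegId.LF, (True, False): LegId.LH,
                      (False, True): LegId.RF, (False, False): LegId.RH}[
                (side_left, fore)]
        labeled[ev.leg].append(ev)
        out.append(ev)
    return out


# ---------------------------------------------------------------------------
# step cycles
# ---------------------------------------------------------------------------


def build_step_cycles(events: Sequence[StanceEvent],
                      cfg: TrialConfig) -> list[StepCycle]:
    """One cycle per consecutive same-leg stance pair (onset-to-onset).

    The swing is attributed to the cycle that begins with the stance
    preceding it, so duty factor = stance_time / period.  Step length is the
    distance between consecutive mean centroids in mm.  The last event of
    each leg starts no cycle.
    """
    fr = cfg.frame_rate_hz
    cycles: list[StepCycle] = []
    for leg in LEGS:
        evs = sorted((e for e in events if e.leg == leg),
                     key=lambda e: e.onset_frame)
        for a, b in zip(evs, evs[1:]):
            if b.onset_frame <= a.offset_frame:
                raise ValueError(
                    f"overlapping stance events on leg {leg.value}: "
                    f"[{a.onset_frame},{a.offset_frame}] then "
                    f"[{b.onset_frame},{b.offset_frame}]")
            stance_frames = a.n_frames
            swing_frames = b.onset_frame - a.offset_frame - 1
            period_frames = b.onset_frame - a.onset_frame
            dx = b.mean_centroid[0] - a.mean_centroid[0]
            dy = b.mean_centroid[1] - a.mean_centroid[1]
            step_mm = float(np.hypot(dx, dy)) * 10.0 / cfg.px_per_cm
            cycles.append(StepCycle(
                leg=leg,
                stance_onset=a.onset_frame,
                stance_offset=a.offset_frame,
                next_stance_onset=b.onset_frame,
                stance_time=stance_frames / fr,
                swing_time=swing_frames / fr,
                period=period_frames / fr,
                step_length=step_mm,
                degenerate=swing_frames == 0,
            ))
    return cycles
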