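"""Trial pipeline and report writers: CSV tables and summary images.

``track_frames``/``analyze_trial`` are the library pipeline; the ``run_*``
functions wrap them with file I/O for the command-line interface.  Every
float written to CSV uses 6 significant digits so re-running a command on
unchanged inputs is byte-identical; missing values are written as the
explicit marker ``undefined`` rather than being skipped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import coordination as coord
from . import kinematics as kin
from .config import TrialConfig
from .segmentation import (BodyPose, FootprintBlob, FrameImage,
                           build_background_two_pass, classify_pixels,
                           decompose_body, extract_footprints, load_frames)
from .tracking import (LEGS, LegId, StanceEvent, StepCycle,
                       assign_leg_identity, build_step_cycles, link_blobs)

log = logging.getLogger("ftirgait")
log.addHandler(logging.NullHandler())
log.propagate = False

LEG_COLORS = {LegId.LF: "#e6c800", LegId.LH: "#1f77d0",
              LegId.RF: "#e07020", LegId.RH: "#2ca02c"}

#: parameter rows every trial summary must contain (or mark undefined)
SUMMARY_PARAMETERS = (
    "speed_avg_cm_s", "frequency_hz", "period_ms", "swing_speed_m_s",
    "step_length_mm", "swing_time_s", "stance_time_s", "duty_factor",
    "aep_longitudinal", "aep_lateral", "pep_longitudinal", "pep_lateral",
    "footprint_clustering_aep", "footprint_clustering_pep",
    "stance_linearity_index", "body_linearity_index_mm",
    "index_no_swing", "index_single", "index_diagonal", "index_lateral",
    "index_front_or_hind", "index_three_leg", "index_all_legs",
    "phase_fore", "phase_hind", "footprint_intensity", "footprint_area_cm2",
    "gait_regime",
)


def _fmt(x) -> str:
    if x is None:
        return "undefined"
    if isinstance(x, str):
        return x
    xf = float(x)
    if math.isnan(xf):
        return "undefined"
    return f"{xf:.6g}"


def _write_csv(path: Path, header: Sequence[str],
               rows: Iterable[Sequence]) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(",".join(header) + "\n")
        for row in rows:
            fh.write(",".join(_fmt(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# tracking pipeline
# ---------------------------------------------------------------------------


@dataclass
class TrackResult:
    cfg: TrialConfig
    poses: dict[int, BodyPose]
    events: list[StanceEvent]
    n_frames: int
    frame_shape: tuple[int, ...]


def track_frames(frames: Sequence[FrameImage],
                 cfg: TrialConfig) -> TrackResult:
    """Segment every frame, decompose the body and link footprints to legs."""
    bg = build_background_two_pass(frames, cfg)
    poses: dict[int, BodyPose] = {}
    pose_list: list[BodyPose] = []
    blobs_by_frame: dict[int, list[FootprintBlob]] = {}
    for fr in frames:
        masks = classify_pixels(fr, bg, cfg)
        pose = decompose_body(masks, cfg, frame_index=fr.index, prev=pose_list)
        if pose is not None:
            poses[fr.index] = pose
            pose_list.append(pose)
            for flag in pose.flags:
                log.warning("frame %d: %s", fr.index, flag)
        else:
            log.warning("frame %d: untracked (no body component)", fr.index)
        blobs_by_frame[fr.index] = extract_footprints(masks, fr, cfg)
    events = link_blobs(blobs_by_frame, cfg)
    if poses:
        events = assign_leg_identity(events, poses, cfg)
        for ev in events:
            for flag in ev.flags:
                log.warning("event at frame %d: %s", ev.onset_frame, flag)
    return TrackResult(cfg=cfg, poses=poses, events=events,
                       n_frames=len(frames),
                       frame_shape=frames[0].pixels.shape)


# ---------------------------------------------------------------------------
# analysis
# ---------------------------------------------------------------------------


@dataclass
class TrialSummary:
    """One value (or mean +/- SD) per quantified gait parameter."""

    values: dict[str, object] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    undefined: dict[str, str] = field(default_factory=dict)

    def set(self, name: str, value, sd: Optional[float] = None) -> None:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            self.undefined.setdefault(name, "not measurable")
            self.values[name] = None
        else:
            self.values[name] = value
            if sd is not None:
                self.sds[name] = sd

    def mark_undefined(self, name: str, reason: str) -> None:
        self.values[name] = None
        self.undefined[name] = reason

    def __getitem__(self, name: str):
        return self.values[name]

    def rows(self):
        for name in SUMMARY_PARAMETERS:
            sd = self.sds.get(name)
            yield (name, self.values.get(name), "" if sd is None else sd,
                   self.undefined.get(name, ""))


@dataclass
class TrialAnalysis:
    cfg: TrialConfig
    cycles: list[StepCycle]
    speed: Optional[kin.SpeedSeries]
    traces: list[coord.StanceTrace]
    categories: dict[int, str]
    indexes: Optional[coord.CombinationIndexes]
    phase_fore: Optional[coord.PhaseEstimate]
    phase_hind: Optional[coord.PhaseEstimate]
    tail: "object"
    summary: TrialSummary


def _mean_sd(vals: Sequence[float]) -> tuple[Optional[float], Optional[float]]:
    v = [x for x in vals if x is not None and not math.isnan(x)]
    if not v:
        return None, None
    return float(np.mean(v)), (float(np.std(v)) if len(v) > 1 else 0.0)


def analyze_trial(track: TrackResult) -> TrialAnalysis:
    """Derive every per-trial gait parameter from tracked poses and events."""
    cfg = track.cfg
    events = [e for e in track.events if e.leg is not None]
    cycles = build_step_cycles(events, cfg)
    summary = TrialSummary()

    speed = None
    if len(track.poses) >= 3:
        try:
            speed = kin.instantaneous_speed(track.poses, cfg)
        except ValueError as exc:
            log.warning("speed series unavailable: %s", exc)
    if speed is not None:
        summary.set("speed_avg_cm_s", speed.average)
    else:
        summary.mark_undefined("speed_avg_cm_s", "too few tracked poses")

    if cycles:
        duties = [kin.duty_factor(c) for c in cycles]
        m, sd = _mean_sd(duties)
        summary.set("duty_factor", m, sd)
        summary.set("gait_regime", kin.classify_gait_regime(m))
        summary.set("period_ms", *_mean_sd([c.period * 1000 for c in cycles]))
        summary.set("frequency_hz", *_mean_sd([1.0 / c.period for c in cycles]))
        summary.set("stance_time_s", *_mean_sd([c.stance_time for c in cycles]))
        summary.set("swing_time_s", *_mean_sd(
            [c.swing_time for c in cycles if not c.degenerate]))
        summary.set("step_length_mm", *_mean_sd([c.step_length for c in cycles]))
        sw = [kin.swing_speed(c) for c in cycles]
        summary.set("swing_speed_m_s", *_mean_sd([s for s in sw if s is not None]))
    else:
        for name in ("duty_factor", "gait_regime", "period_ms", "frequency_hz",
                     "stance_time_s", "swing_time_s", "step_length_mm",
                     "swing_speed_m_s"):
            summary.mark_undefined(name, "zero complete step cycles")

    traces = [coord.build_stance_trace(e, track.poses, cfg)
              for e in events] if track.poses else []
    usable = [t for t in traces if not t.flagged]
    if usable:
        summary.set("aep_longitudinal",
                    *_mean_sd([t.aep.longitudinal for t in usable]))
        summary.set("aep_lateral",
                    *_mean_sd([abs(t.aep.lateral) for t in usable]))
        summary.set("pep_longitudinal",
                    *_mean_sd([t.pep.longitudinal for t in usable]))
        summary.set("pep_lateral",
                    *_mean_sd([abs(t.pep.lateral) for t in usable]))
    else:
        for name in ("aep_longitudinal", "aep_lateral", "pep_longitudinal",
                     "pep_lateral"):
            summary.mark_undefined(name, "no usable stance traces")
    for ep in ("aep", "pep"):
        v = coord.footprint_clustering(traces, ep.upper())
        if v is None:
            summary.mark_undefined(f"footprint_clustering_{ep}",
                                   "no leg with at least 2 steps")
        else:
            summary.set(f"footprint_clustering_{ep}", v)
    lin = coord.trial_stance_linearity(traces, cfg.linearity_smooth_win)
    if lin is None:
        summary.mark_undefined(
            "stance_linearity_index",
            "no stance trace at least as long as the smoothing window")
    else:
        summary.set("stance_linearity_index", lin)
    summary.set("body_linearity_index_mm",
                coord.body_linearity_index(track.poses, cfg,
                                           cfg.linearity_smooth_win))

    categories: dict[int, str] = {}
    indexes = None
    if events:
        first = min(e.onset_frame for e in events)
        last = max(e.offset_frame for e in events)
        flags = coord.stance_flags_by_frame(events, (first, last))
        # frames without a tracked pose are unclassifiable
        categories = {f: coord.frame_combination(fl)
                      for f, fl in flags.items()
                      if not track.poses or f in track.poses}
    if categories:
        indexes = coord.combination_indexes(
            [categories[f] for f in sorted(categories)])
        for cat in coord.CATEGORIES:
            summary.set(f"index_{cat}", indexes[cat])
    else:
        for cat in coord.CATEGORIES:
            summary.mark_undefined(f"index_{cat}", "no classifiable frames")

    def _phase(ref: LegId, partner: LegId, pair: str):
        refc = [c for c in cycles if c.leg == ref]
        onsets = [e.onset_frame for e in events if e.leg == partner]
        return coord.contralateral_phase(refc, onsets, pair)

    phase_fore = _phase(LegId.LF, LegId.RF, "fore") if cycles else None
    phase_hind = _phase(LegId.LH, LegId.RH, "hind") if cycles else None
    if phase_fore is not None:
        summary.set("phase_fore", phase_fore.mean_phase, phase_fore.dispersion)
    else:
        summary.mark_undefined("phase_fore", "too few paired cycles")
    if phase_hind is not None:
        summary.set("phase_hind", phase_hind.mean_phase, phase_hind.dispersion)
    else:
        summary.mark_undefined("phase_hind", "too few paired cycles")

    areas, intens = [], []
    for e in events:
        sel = e.areas > 0
        areas.extend((e.areas[sel] / cfg.px_per_cm ** 2).tolist())
        intens.extend(e.brightness[sel].tolist())
    summary.set("footprint_area_cm2", *_mean_sd(areas))
    summary.set("footprint_intensity", *_mean_sd(intens))

    tail = coord.tail_metrics(track.poses, cfg) if track.poses else None
    return TrialAnalysis(cfg=cfg, cycles=cycles, speed=speed, traces=traces,
                         categories=categories, indexes=indexes,
                         phase_fore=phase_fore, phase_hind=phase_hind,
                         tail=tail, summary=summary)


# ---------------------------------------------------------------------------
# CSV writers
# ---------------------------------------------------------------------------


def write_poses_csv(poses: Mapping[int, BodyPose], path: Path) -> None:
    header = ["frame", "nose_x", "nose_y", "head_x", "head_y",
              "center_x", "center_y", "orientation_rad",
              "back_x", "back_y", "tail_base_x", "tail_base_y",
              "tail1_x", "tail1_y", "tail2_x", "tail2_y", "tail3_x", "tail3_y",
              "body_length_cm", "flags"]
    rows = []
    for f in sorted(poses):
        p = poses[f]
        tb = p.tail_base or (None, None)
        tp = list(p.tail_points) + [(None, None)] * (3 - len(p.tail_points))
        rows.append([f, p.nose[0], p.nose[1], p.head_center[0],
                     p.head_center[1], p.body_center[0], p.body_center[1],
                     p.body_orientation, p.back_point[0], p.back_point[1],
                     tb[0], tb[1], tp[0][0], tp[0][1], tp[1][0], tp[1][1],
                     tp[2][0], tp[2][1], p.body_length,
                     ";".join(p.flags) if p.flags else ""])
    _write_csv(path, header, rows)


def write_events_csv(events: Sequence[StanceEvent], path: Path) -> None:
    header = ["leg", "onset_frame", "offset_frame", "mean_x", "mean_y",
              "peak_brightness", "n_frames", "flags"]
    rows = []
    for e in sorted(events, key=lambda e: (e.onset_frame, e.mean_centroid[0])):
        rows.append([e.leg.value if e.leg else "unassigned",
                     e.onset_frame, e.offset_frame,
                     e.mean_centroid[0], e.mean_centroid[1],
                     float(e.brightness.max()), e.n_frames,
                     ";".join(e.flags) if e.flags else ""])
    _write_csv(path, header, rows)


def write_analysis_csvs(track: TrackResult, ana: TrialAnalysis,
                        out: Path) -> None:
    cfg = track.cfg
    events = [e for e in track.events if e.leg is not None]

    _write_csv(out / "summary.csv",
               ["parameter", "value", "sd", "undefined_reason"],
               ana.summary.rows())

    rows = []
    for c in ana.cycles:
        rows.append([c.leg.value, c.stance_onset, c.stance_offset,
                     c.next_stance_onset, c.stance_time, c.swing_time,
                     c.period, c.step_length, kin.duty_factor(c),
                     kin.swing_speed(c)])
    _write_csv(out / "cycles.csv",
               ["leg", "stance_onset", "stance_offset", "next_stance_onset",
                "stance_time_s", "swing_time_s", "period_s", "step_length_mm",
                "duty_factor", "swing_speed_m_s"], rows)

    if ana.speed is not None:
        speed_of = dict(zip(ana.speed.frames.tolist(),
                            ana.speed.instantaneous.tolist()))
    else:
        speed_of = {}
    rows = [[f, f / cfg.frame_rate_hz, ana.categories.get(f, "undefined"),
             speed_of.get(f)] for f in sorted(ana.categories)]
    _write_csv(out / "gait_vs_time.csv",
               ["frame", "time_s", "category", "speed_cm_s"], rows)

    rows = [[f, f / cfg.frame_rate_hz] +
            [1 if ana.categories[f] == c else 0 for c in coord.CATEGORIES]
            for f in sorted(ana.categories)]
    _write_csv(out / "combination_traces.csv",
               ["frame", "time_s", *coord.CATEGORIES], rows)

    if ana.speed is not None:
        rows = [[int(f), int(f) / cfg.frame_rate_hz, s]
                for f, s in zip(ana.speed.frames, ana.speed.instantaneous)]
    else:
        rows = []
    _write_csv(out / "speed.csv", ["frame", "time_s", "speed_cm_s"], rows)

    rows = []
    for i, t in enumerate(ana.traces):
        for j, f in enumerate(t.frames):
            rows.append([i, t.leg.value if t.leg else "unassigned", int(f),
                         t.points[j, 0], t.points[j, 1],
                         1 if j == 0 else 0, 1 if j == len(t.frames) - 1 else 0,
                         1 if t.flagged else 0])
    _write_csv(out / "stance_traces.csv",
               ["trace", "leg", "frame", "longitudinal", "lateral",
                "is_aep", "is_pep", "flagged"], rows)

    rows = []
    for i, e in enumerate(events):
        frames = np.arange(e.onset_frame, e.offset_frame + 1)
        cx, cy, th, bl = coord._interpolated_pose_table(track.poses, frames) \
            if track.poses else (None,) * 4
        for j, f in enumerate(frames):
            if cx is None:
                continue
            dx = e.centroids[j, 0] - cx[j]
            dy = e.centroids[j, 1] - cy[j]
            c, s = np.cos(th[j]), np.sin(th[j])
            par = (dx * c + dy * s) / cfg.px_per_cm
            perp = (-dx * s + dy * c) / cfg.px_per_cm
            rows.append([i, e.leg.value, int(f),
                         float(np.hypot(dx, dy)) / cfg.px_per_cm, par, perp])
    _write_csv(out / "footprint_distances.csv",
               ["event", "leg", "frame", "distance_cm", "parallel_cm",
                "perpendicular_cm"], rows)

    rows = []
    for i, e in enumerate(events):
        ps = coord.pressure_series(e, cfg)
        for _, r in ps.iterrows():
            rows.append([i, e.leg.value, int(r["frame"]), r["time_s"],
                         r["area_cm2"], r["intensity"], r["pressure"]])
    _write_csv(out / "pressure.csv",
               ["event", "leg", "frame", "time_s", "area_cm2", "intensity",
                "pressure"], rows)

    write_events_csv(events, out / "footprints.csv")

    if ana.tail is not None and len(ana.tail):
        cols = list(ana.tail.columns)
        _write_csv(out / "tail_metrics.csv", cols,
                   ana.tail.itertuples(index=False))
    else:
        _write_csv(out / "tail_metrics.csv",
                   ["frame", "time_s", "proximal_vs_body", "middle_vs_body",
                    "distal_vs_body", "proximal_vs_middle", "distal_vs_middle",
                    "tail_perp_velocity_cm_s"], [])


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------


def write_report_images(track: TrackResult, ana: TrialAnalysis, out: Path,
                        frames: Optional[Sequence[FrameImage]] = None) -> None:
    cfg = track.cfg
    events = [e for e in track.events if e.leg is not None]
    H, W = track.frame_shape[:2]

    # footprint-pattern heat map: per-pixel max fTIR brightness + body path
    if frames is not None:
        acc = np.zeros((H, W))
        for fr in frames:
            b = fr.channels().mean(axis=2)
            np.maximum(acc, b, out=acc)
    else:
        acc = np.zeros((H, W))
        for e in events:
            for j in range(e.n_frames):
                x, y = e.centroids[j]
                acc[int(round(y)), int(round(x))] = max(
                    acc[int(round(y)), int(round(x))], e.brightness[j])
    fig, ax = plt.subplots(figsize=(10, 2.2))
    ax.imshow(acc, cmap="hot", origin="upper",
              extent=(0, W / cfg.px_per_cm, H / cfg.px_per_cm, 0))
    if track.poses:
        path = np.array([track.poses[f].body_center
                         for f in sorted(track.poses)]) / cfg.px_per_cm
        ax.plot(path[:, 0], path[:, 1], color="w", lw=0.8)
    ax.set_xlabel("cm")
    ax.set_ylabel("cm")
    fig.savefig(out / "footprint_pattern_heatmap.png", dpi=120)
    plt.close(fig)

    # color-coded footprint pattern, one color per leg
    fig, ax = plt.subplots(figsize=(10, 2.2))
    ax.set_facecolor("black")
    for e in events:
        x, y = e.mean_centroid
        r = np.sqrt(max(e.areas.max(), 1) / np.pi) / cfg.px_per_cm
        ax.add_patch(plt.Circle((x / cfg.px_per_cm, y / cfg.px_per_cm), r,
                                color=LEG_COLORS[e.leg]))
    if track.poses:
        path = np.array([track.poses[f].body_center
                         for f in sorted(track.poses)]) / cfg.px_per_cm
        ax.plot(path[:, 0], path[:, 1], color="w", lw=0.8)
    ax.set_xlim(0, W / cfg.px_per_cm)
    ax.set_ylim(H / cfg.px_per_cm, 0)
    ax.set_xlabel("cm")
    fig.savefig(out / "footprint_pattern_colored.png", dpi=120)
    plt.close(fig)

    # gait diagram: stance bars per leg + instantaneous speed
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(10, 3.5), sharex=True,
                                   height_ratios=[2, 1])
    for i, leg in enumerate(LEGS):
        spans = [(e.onset_frame / cfg.frame_rate_hz,
                  e.n_frames / cfg.frame_rate_hz)
                 for e in events if e.leg == leg]
        ax1.broken_barh(spans, (i + 0.1, 0.8), color=LEG_COLORS[leg])
    ax1.set_yticks([i + 0.5 for i in range(4)],
                   [leg.value for leg in LEGS])
    ax1.set_ylabel("stance")
    if ana.speed is not None:
        ax2.plot(ana.speed.frames / cfg.frame_rate_hz,
                 ana.speed.instantaneous, lw=0.9)
    ax2.set_xlabel("time (s)")
    ax2.set_ylabel("cm/s")
    fig.savefig(out / "gait_diagram.png", dpi=120)
    plt.close(fig)

    # per-stance frame strips and full-stance footprints need the raw frames
    if frames is not None:
        frame_of = {fr.index: fr for fr in frames}
        half = max(4, int(round(1.2 * cfg.px_per_cm)))
        for leg in LEGS:
            evs = [e for e in events if e.leg == leg]
            if not evs:
                continue
            strips = []
            stamps = []
            for e in evs:
                picks = np.linspace(e.onset_frame, e.offset_frame,
                                    min(10, e.n_frames)).round().astype(int)
                crops = []
                for f in picks:
                    fr = frame_of.get(int(f))
                    if fr is None:
                        continue
                    x, y = e.centroids[int(f) - e.onset_frame]
                    b = fr.channels().mean(axis=2)
                    crop = np.zeros((2 * half, 2 * half))
                    ys0, ys1 = int(round(y)) - half, int(round(y)) + half
                    xs0, xs1 = int(round(x)) - half, int(round(x)) + half
                    sy0, sy1 = max(0, ys0), min(b.shape[0], ys1)
                    sx0, sx1 = max(0, xs0), min(b.shape[1], xs1)
                    crop[sy0 - ys0:sy1 - ys0, sx0 - xs0:sx1 - xs0] = \
                        b[sy0:sy1, sx0:sx1]
                    crops.append(crop)
                if crops:
                    strips.append(np.concatenate(crops, axis=1))
                # max projection = full-stance footprint
                stamp = np.zeros((2 * half, 2 * half))
                for f in range(e.onset_frame, e.offset_frame + 1):
                    fr = frame_of.get(f)
                    if fr is None:
                        continue
                    x, y = e.centroids[f - e.onset_frame]
                    b = fr.channels().mean(axis=2)
                    ys0, xs0 = int(round(y)) - half, int(round(x)) - half
                    sy0, sy1 = max(0, ys0), min(b.shape[0], ys0 + 2 * half)
                    sx0, sx1 = max(0, xs0), min(b.shape[1], xs0 + 2 * half)
                    sub = np.zeros((2 * half, 2 * half))
                    sub[sy0 - ys0:sy1 - ys0, sx0 - xs0:sx1 - xs0] = \
                        b[sy0:sy1, sx0:sx1]
                    np.maximum(stamp, sub, out=stamp)
                stamps.append(stamp)
            if strips:
                width = max(s.shape[1] for s in strips)
                padded = [np.pad(s, ((0, 0), (0, width - s.shape[1])))
                          for s in strips]
                strip = np.concatenate(padded, axis=0)
                _save_gray(out / f"stance_strip_{leg.value}.png", strip)
            if stamps:
                _save_gray(out / f"footprints_{leg.value}.png",
                           np.concatenate(stamps, axis=1))


def _save_gray(path: Path, arr: np.ndarray) -> None:
    import imageio.v3 as iio
    a = np.clip(arr, 0, 255).astype(np.uint8)
    iio.imwrite(path, a)


def write_overlay_images(frames: Sequence[FrameImage], track: TrackResult,
                         out: Path, every: int = 25) -> None:
    """Debug overlays: body contour and color-coded footprint centroids."""
    import imageio.v3 as iio
    from scipy import ndimage as ndi
    out.mkdir(parents=True, exist_ok=True)
    leg_rgb = {LegId.LF: (230, 200, 0), LegId.LH: (31, 119, 208),
               LegId.RF: (224, 112, 32), LegId.RH: (44, 160, 44)}
    for fr in frames[::every]:
        img = fr.channels().mean(axis=2)
        rgb = np.stack([img] * 3, axis=2).astype(np.float64)
        pose = track.poses.get(fr.index)
        if pose is not None:
            x, y = int(round(pose.body_center[0])), int(round(pose.body_center[1]))
            rgb[max(0, y - 1):y + 2, max(0, x - 1):x + 2] = (255, 0, 0)
        for e in track.events:
            if e.leg is None or not e.onset_frame <= fr.index <= e.offset_frame:
                continue
            j = fr.index - e.onset_frame
            x, y = int(round(e.centroids[j, 0])), int(round(e.centroids[j, 1]))
            rgb[max(0, y - 2):y + 3, max(0, x - 2):x + 3] = leg_rgb[e.leg]
        iio.imwrite(out / f"overlay_{fr.index:06d}.png",
                    np.clip(rgb, 0, 255).astype(np.uint8))


# ---------------------------------------------------------------------------
# CLI-level runners
# ---------------------------------------------------------------------------


def run_track(frames_dir: str | Path, config_path: str | Path,
              out_dir: str | Path, debug_overlays: bool = False
              ) -> TrackResult:
    """Track a frame directory and write pose/event CSVs."""
    cfg = TrialConfig.load(config_path)
    frames = load_frames(frames_dir, cfg.frame_rate_hz)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logfile(out / "tracking.log")
    track = track_frames(frames, cfg)
    write_poses_csv(track.poses, out / "poses.csv")
    write_events_csv(track.events, out / "events.csv")
    if debug_overlays:
        write_overlay_images(frames, track, out / "overlays")
    return track


def run_analyze(frames_dir: str | Path, config_path: str | Path,
                out_dir: str | Path, debug_overlays: bool = False
                ) -> TrialAnalysis:
    """Full pipeline on one trial: track, analyze, write tables and images."""
    cfg = TrialConfig.load(config_path)
    frames = load_frames(frames_dir, cfg.frame_rate_hz)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logfile(out / "tracking.log")
    track = track_frames(frames, cfg)
    write_poses_csv(track.poses, out / "poses.csv")
    write_events_csv(track.events, out / "events.csv")
    ana = analyze_trial(track)
    write_analysis_csvs(track, ana, out)
    write_report_images(track, ana, out, frames=frames)
    if debug_overlays:
        write_overlay_images(frames, track, out / "overlays")
    return ana


def _setup_logfile(path: Path) -> None:
    for h in list(log.handlers):
        log.removeHandler(h)
    h = logging.FileHandler(path, mode="w")
    h.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(h)
    log.setLevel(logging.WARNING)
    log.propagate = False


def run_report(summaries: Sequence[TrialSummary],
               out_dir: str | Path) -> dict:
    """Cohort tables and speed fits across two or more analyzed trials."""
    if len(summaries) < 2:
        raise ValueError("need at least 2 trials for a cohort report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for i, s in enumerate(summaries):
        rows.append([i] + [s.values.get(p) for p in SUMMARY_PARAMETERS])
    _write_csv(out / "trials.csv", ["trial", *SUMMARY_PARAMETERS], rows)

    def _pairs(param):
        out = []
        for s in summaries:
            v = s.values.get("speed_avg_cm_s")
            y = s.values.get(param)
            if v is not None and y is not None:
                out.append((float(v), float(y)))
        return out

    fits: dict[str, dict] = {}

    def _linfit(param):
        pts = _pairs(param)
        if len(pts) < 2:
            return None
        v = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        if np.ptp(v) < 1e-12:
            return {"slope": None, "intercept": None, "flag": "zero speed span"}
        slope, intercept = np.polyfit(v, y, 1)
        flag = "zero slope" if abs(slope) < 1e-12 else ""
        return {"slope": float(slope), "intercept": float(intercept),
                "flag": flag}

    fits["step_length_mm"] = _linfit("step_length_mm")
    fits["swing_time_s"] = _linfit("swing_time_s")
    fits["swing_speed_m_s"] = _linfit("swing_speed_m_s")
    fits["duty_factor"] = _linfit("duty_factor")
    if fits["duty_factor"] and fits["duty_factor"]["slope"] is not None:
        sl, ic = fits["duty_factor"]["slope"], fits["duty_factor"]["intercept"]
        if sl < 0:
            fits["duty_factor"]["crossing_speed_cm_s"] = \
                kin.crossing_speed_from_coefficients(sl, ic)
        else:
            fits["duty_factor"]["flag"] = "non-negative slope, no crossing"
    stexp = kin.fit_stance_time_exponential(_pairs("stance_time_s"))
    fits["stance_time_s"] = (
        {"a": stexp[0], "b": stexp[1], "c": stexp[2], "flag": ""}
        if stexp else {"flag": "exponential fit failed"})

    rows = []
    for param, fit in fits.items():
        if fit is None:
            rows.append([param, "", "", "", "no data"])
            continue
        rows.append([param,
                     fit.get("slope", fit.get("a")),
                     fit.get("intercept", fit.get("b")),
                     fit.get("crossing_speed_cm_s", fit.get("c")),
                     fit.get("flag", "")])
    _write_csv(out / "fits.csv",
               ["parameter", "slope_or_a", "intercept_or_b",
                "crossing_or_c", "flag"], rows)
    return fits
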