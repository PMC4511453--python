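"""Ground-truthed synthetic fTIR walking trials.

The generator emulates what the camera under an fTIR walkway sees: a dark
floor, a mid-intensity body silhouette (ellipse plus tapered tail) gliding
along the walkway, and bright paw-contact spots that appear only while a
foot is on the glass, anchored to the floor for the whole stance (feet do
not slip, unless a slip term is requested).  Every quantity the analysis
pipeline estimates — pose, stance schedule, duty factor, stride, phases —
is recorded exactly as constructed, so recovery can be scored against
known truth without animal data.

Default study conditions: 250 Hz acquisition, 10 px/cm calibration, a
~7 cm (body) mouse with a 6 cm tail trotting at 30 cm/s with 30 mm
strides, duty factor 0.55 and anti-phase contralateral coupling.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np

from .config import TrialConfig
from .segmentation import BodyPose, FrameImage
from .tracking import LEGS, LegId

# ---------------------------------------------------------------------------
# specification
# ---------------------------------------------------------------------------

# rendering levels (uint8); the written TrialConfig thresholds match these
BG_LEVEL = 20.0
BODY_LEVEL_ADD = 70.0          # body pixel = BG + 70 = 90
PAW_PEAK = 235.0               # peak Gaussian amplitude added on contact
PAW_SIGMA_CM = 0.25            # Gaussian spot width
TOE_SHIFT_CM = 0.3             # rostral offset of the toe sub-spot
TOE_AMP_FRAC = 0.3             # toe spot peak relative to the main spot
RAMP_FRAC = 0.10               # touchdown amplitude ramp, fraction of stance
RAMP_FLOOR = 0.9               # amplitude multiplier at touchdown

# paw placement in the body frame (fractions of body length / cm lateral)
FORE_AEP_LONG = 0.30           # body lengths anterior of the body center
HIND_AEP_LONG = -0.10
FORE_LAT_CM = 0.7              # cm toward the animal's side
HIND_LAT_CM = 1.0


@dataclass
class SyntheticGaitSpec:
    """Parameters of one synthetic trial; a fixed seed reproduces it exactly."""

    speed: float = 30.0               # cm/s
    stride_length: float = 30.0       # mm
    duty: float = 0.55                # stance fraction of the cycle
    pair_phase: float = 0.5           # contralateral offset; 0.5 = anti-phase
    diagonal: bool = True             # trot patterning (False: pace)
    phase_offsets: Optional[dict] = None   # explicit per-leg phases, overrides
    body_length_cm: float = 7.0
    body_width_cm: float = 2.5
    tail_length_cm: float = 6.0
    frame_rate_hz: float = 250.0
    px_per_cm: float = 10.0
    n_cycles: int = 8
    pixel_sigma: float = 2.0          # additive image noise SD
    aep_jitter_cm: float = 0.05       # touchdown position jitter SD
    pep_jitter_cm: float = 0.0        # slip drift over the stance, SD of total
    speed_mod_amplitude: float = 0.0  # fractional sinusoidal speed modulation
    tail_sway_cm: float = 0.0         # lateral sway amplitude at the tail tip
    tail_sway_hz: float = 0.0
    color: bool = False               # body in red, paws in green
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.duty < 1.0:
            raise ValueError("duty must lie in (0, 1)")
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if self.n_cycles < 2:
            raise ValueError("need at least 2 cycles")

    def leg_phases(self) -> dict[LegId, float]:
        if self.phase_offsets is not None:
            return {LegId(k): float(v) for k, v in self.phase_offsets.items()}
        p = self.pair_phase % 1.0
        if self.diagonal:   # trot: diagonal pairs in sync
            return {LegId.LF: 0.0, LegId.RH: 0.0, LegId.RF: p, LegId.LH: p}
        return {LegId.LF: 0.0, LegId.LH: 0.0, LegId.RF: p, LegId.RH: p}


@dataclass
class StanceTruth:
    leg: LegId
    onset: int                        # frame, inclusive
    offset: int                       # frame, inclusive
    anchor_path: np.ndarray           # (n_frames, 2) px; constant unless slip


@dataclass
class GroundTruth:
    spec: SyntheticGaitSpec
    height: int
    width: int
    n_frames: int
    period_frames: int
    stance_frames: int
    center_x: np.ndarray              # px per frame
    center_y: float                   # px, constant
    stances: list[StanceTruth]
    background_level: float
    # parameters as realized by the integer-frame schedule
    duty_true: float = 0.0
    stride_mm_true: float = 0.0
    speed_avg_true: float = 0.0       # cm/s over the rendered frames
    phase_fore_true: float = 0.0
    phase_hind_true: float = 0.0

    def poses(self, cfg: Optional[TrialConfig] = None) -> dict[int, BodyPose]:
        """True per-frame body poses in the segmentation pose format."""
        ppc = self.spec.px_per_cm
        a = self.spec.body_length_cm / 2.0 * ppc
        out = {}
        for f in range(self.n_frames):
            cx = float(self.center_x[f])
            tb = (cx - a, self.center_y)
            tail_pts, tail_or = _tail_geometry(self.spec, f, tb)
            out[f] = BodyPose(
                frame=f, nose=(cx + a, self.center_y),
                head_center=(cx + 0.8 * a, self.center_y),
                head_direction=(1.0, 0.0),
                body_center=(cx, self.center_y), body_orientation=0.0,
                back_point=((cx + tb[0]) / 2.0, self.center_y),
                back_direction=(1.0, 0.0),
                tail_base=tb, tail_points=tail_pts, tail_orientations=tail_or,
                body_length=self.spec.body_length_cm)
        return out

    def contacts_at(self, f: int) -> dict[LegId, bool]:
        flags = {leg: False for leg in LEGS}
        for st in self.stances:
            if st.onset <= f <= st.offset:
                flags[st.leg] = True
        return flags

    def trial_config(self) -> TrialConfig:
        """Detection thresholds matched to the rendering levels."""
        if self.spec.color:
            return TrialConfig(
                frame_rate_hz=self.spec.frame_rate_hz,
                px_per_cm=self.spec.px_per_cm,
                bg_tolerance=(12.0, 12.0, 12.0),
                body_rgb_min=(60.0, 0.0, 0.0),
                body_rgb_max=(160.0, 60.0, 60.0),
                footprint_rgb_min=(0.0, 170.0, 0.0),
                footprint_rgb_max=(255.0, 255.0, 255.0))
        return TrialConfig(frame_rate_hz=self.spec.frame_rate_hz,
                           px_per_cm=self.spec.px_per_cm)


def _tail_geometry(spec: SyntheticGaitSpec, frame: int,
                   tail_base: tuple[float, float]
                   ) -> tuple[list[tuple[float, float]], list[float]]:
    """True tail quarter points and local orientations (with optional sway)."""
    ppc = spec.px_per_cm
    Lt = spec.tail_length_cm * ppc
    t = frame / spec.frame_rate_hz
    sway = spec.tail_sway_cm * ppc * np.sin(2 * np.pi * spec.tail_sway_hz * t) \
        if spec.tail_sway_cm > 0 else 0.0
    pts, orients = [], []
    for frac in (0.25, 0.5, 0.75):
        s = frac * Lt
        y_off = sway * frac          # linear ramp base -> tip
        pts.append((tail_base[0] - s, tail_base[1] + y_off))
        # local direction oriented base-ward (aligned with the body axis for
        # a straight tail): d/ds of (-s, sway*s/Lt) negated
        orients.append(float(np.arctan2(-sway / Lt, 1.0)))
    return pts, orients


# ---------------------------------------------------------------------------
# ground-truth construction
# ---------------------------------------------------------------------------


def generate_ground_truth(spec: SyntheticGaitSpec) -> GroundTruth:
    """Build the exact stance schedule, body trajectory and true parameters.

    The step period is rounded to an integer number of frames; all "true"
    values are recorded from the integer-frame schedule actually emitted,
    not from the nominal request, so recovery scores measure the pipeline
    and not quantization.
    """
    fr, ppc = spec.frame_rate_hz, spec.px_per_cm
    period_frames = int(round(fr * (spec.stride_length / 10.0) / spec.speed))
    if period_frames < 4:
        raise ValueError("stride/speed give a period under 4 frames")
    stance_frames = int(round(spec.duty * period_frames))
    stance_frames = min(max(stance_frames, 1), period_frames - 1)
    n_frames = spec.n_cycles * period_frames + stance_frames + 1
    if spec.n_cycles < 2:
        raise ValueError("spec yields fewer than 2 cycles")

    # body-center trajectory (cm -> px); sinusoidal modulation integrates to
    # zero over each full period so the average speed stays spec.speed
    tvec = np.arange(n_frames) / fr
    period_s = period_frames / fr
    if spec.speed_mod_amplitude > 0:
        w = 2 * np.pi / period_s
        x_cm = spec.speed * tvec + spec.speed * spec.speed_mod_amplitude / w \
            * (1.0 - np.cos(w * tvec))
    else:
        x_cm = spec.speed * tvec

    a_px = spec.body_length_cm / 2.0 * ppc
    half_h = max(spec.body_width_cm / 2.0 * ppc,
                 (HIND_LAT_CM + 0.5) * ppc,
                 spec.tail_sway_cm * ppc + 3.0) + 5.0
    height = int(2 * np.ceil(half_h))
    center_y = height / 2.0
    x0_px = (spec.tail_length_cm + spec.body_length_cm / 2.0 + 1.0) * ppc
    center_x = x0_px + x_cm * ppc
    fore_long_px = FORE_AEP_LONG * spec.body_length_cm * ppc
    width = int(np.ceil(center_x[-1] + a_px + fore_long_px + 4 * PAW_SIGMA_CM * ppc + 8))

    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 17]))
    phases = spec.leg_phases()
    stances: list[StanceTruth] = []
    for leg in LEGS:
        fore = leg in (LegId.LF, LegId.RF)
        left = leg in (LegId.LF, LegId.LH)
        long_px = (FORE_AEP_LONG if fore else HIND_AEP_LONG) \
            * spec.body_length_cm * ppc
        lat_px = (FORE_LAT_CM if fore else HIND_LAT_CM) * ppc * (1 if left else -1)
        shift = int(round(phases[leg] * period_frames))
        for k in range(spec.n_cycles):
            onset = k * period_frames + shift
            offset = onset + stance_frames - 1
            if offset >= n_frames:
                break
            jit = rng.normal(0.0, spec.aep_jitter_cm * ppc, size=2)
            anchor = np.array([center_x[onset] + long_px + jit[0],
                               center_y + lat_px + jit[1]])
            path = np.tile(anchor, (stance_frames, 1))
            if spec.pep_jitter_cm > 0:
                slip = rng.normal(0.0, spec.pep_jitter_cm * ppc, size=2)
                frac = np.linspace(0.0, 1.0, stance_frames)[:, None]
                path = path + frac * slip[None, :]
            stances.append(StanceTruth(leg, onset, offset, path))

    gt = GroundTruth(
        spec=spec, height=height, width=width, n_frames=n_frames,
        period_frames=period_frames, stance_frames=stance_frames,
        center_x=center_x, center_y=center_y, stances=stances,
        background_level=BG_LEVEL)
    gt.duty_true = stance_frames / period_frames
    gt.stride_mm_true = (x_cm[period_frames] - x_cm[0]) * 10.0
    gt.speed_avg_true = (x_cm[-1] - x_cm[0]) / tvec[-1]
    sh = {leg: int(round(phases[leg] * period_frames)) for leg in LEGS}
    gt.phase_fore_true = ((sh[LegId.RF] - sh[LegId.LF]) % period_frames) \
        / period_frames
    gt.phase_hind_true = ((sh[LegId.RH] - sh[LegId.LH]) % period_frames) \
        / period_frames
    return gt


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _paint_disk(img: np.ndarray, cx: float, cy: float, r: float,
                value: float) -> None:
    y0, y1 = max(0, int(cy - r) - 1), min(img.shape[0], int(cy + r) + 2)
    x0, x1 = max(0, int(cx - r) - 1), min(img.shape[1], int(cx + r) + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    sel = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    img[y0:y1, x0:x1][sel] = value


def _render_body(img: np.ndarray, spec: SyntheticGaitSpec, cx: float,
                 cy: float, frame: int) -> None:
    ppc = spec.px_per_cm
    a = spec.body_length_cm / 2.0 * ppc
    b = spec.body_width_cm / 2.0 * ppc
    y0, y1 = max(0, int(cy - b) - 1), min(img.shape[0], int(cy + b) + 2)
    x0, x1 = max(0, int(cx - a) - 1), min(img.shape[1], int(cx + a) + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    sel = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    img[y0:y1, x0:x1][sel] = BG_LEVEL + BODY_LEVEL_ADD
    # tapered tail: disks along the (possibly swaying) tail midline
    Lt = spec.tail_length_cm * ppc
    base = (cx - a, cy)
    t = frame / spec.frame_rate_hz
    sway = spec.tail_sway_cm * ppc * np.sin(2 * np.pi * spec.tail_sway_hz * t) \
        if spec.tail_sway_cm > 0 else 0.0
    n_steps = int(Lt * 2)
    for i in range(n_steps + 1):
        s = i / n_steps * Lt
        r = 2.0 - 1.0 * (s / Lt)          # 4 px wide at base, 2 px at tip
        _paint_disk(img, base[0] - s, base[1] + sway * s / Lt, r,
                    BG_LEVEL + BODY_LEVEL_ADD)


def _spot_amplitude(i: int, n: int) -> tuple[float, float]:
    """Main and toe spot amplitude multipliers at stance frame i of n."""
    ramp_len = max(1, int(np.ceil(RAMP_FRAC * n)))
    main = RAMP_FLOOR + (1.0 - RAMP_FLOOR) * min(1.0, (i + 1) / ramp_len)
    third = 2.0 * n / 3.0
    toe = 0.0
    if i >= third and n > 1:
        toe = TOE_AMP_FRAC * (i - third) / max(1.0, (n - 1) - third)
    return main, toe


def _add_spot(img: np.ndarray, cx: float, cy: float, amp: float,
              sigma: float) -> None:
    # super-Gaussian (flat top, sharp skirt): contact spots have crisp edges
    r = 4.0 * sigma
    y0, y1 = max(0, int(cy - r)), min(img.shape[0], int(cy + r) + 1)
    x0, x1 = max(0, int(cx - r)), min(img.shape[1], int(cx + r) + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    q = ((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma ** 2)
    img[y0:y1, x0:x1] += amp * np.exp(-(q ** 2))


def render_frame(truth: GroundTruth, f: int,
                 rng: Optional[np.random.Generator] = None) -> FrameImage:
    """Render one frame; pass no rng for the noise-free image."""
    spec = truth.spec
    ppc = spec.px_per_cm
    cx = float(truth.center_x[f])
    cy = truth.center_y
    if cx + spec.body_length_cm / 2.0 * ppc > truth.width or \
            cx - (spec.body_length_cm / 2.0 + spec.tail_length_cm) * ppc < 0:
        raise ValueError(f"body exits the frame at frame {f}")
    body = np.full((truth.height, truth.width), BG_LEVEL)
    _render_body(body, spec, cx, cy, f)
    paws = np.zeros_like(body)
    sigma = PAW_SIGMA_CM * ppc
    for st in truth.stances:
        if not st.onset <= f <= st.offset:
            continue
        i = f - st.onset
        n = st.offset - st.onset + 1
        main, toe = _spot_amplitude(i, n)
        ax, ay = st.anchor_path[i]
        _add_spot(paws, ax, ay, main * PAW_PEAK, sigma)
        if toe > 0:
            _add_spot(paws, ax + TOE_SHIFT_CM * ppc, ay, toe * PAW_PEAK, sigma)
    if spec.color:
        img = np.empty((truth.height, truth.width, 3))
        img[..., 0] = body
        img[..., 1] = BG_LEVEL + paws
        img[..., 2] = BG_LEVEL
    else:
        img = body + paws
    if rng is not None and spec.pixel_sigma > 0:
        img = img + rng.normal(0.0, spec.pixel_sigma, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return FrameImage(index=f, time=f / spec.frame_rate_hz, pixels=img)


def render_frames(truth: GroundTruth) -> list[FrameImage]:
    """Render the whole trial with seeded additive noise."""
    rng = np.random.default_rng(
        np.random.SeedSequence([int(truth.spec.seed), 29]))
    return [render_frame(truth, f, rng) for f in range(truth.n_frames)]


def footprint_truth_mask(truth: GroundTruth, f: int,
                         threshold: float = 170.0) -> np.ndarray:
    """Ground-truth footprint mask: noise-free rendering above the threshold."""
    frame = render_frame(truth, f, rng=None)
    ch = frame.channels()
    if truth.spec.color:
        return ch[..., 1] >= threshold
    return ch[..., 0] >= threshold


# ---------------------------------------------------------------------------
# fixture writing
# ---------------------------------------------------------------------------


def _fmt(x) -> str:
    return f"{x:.6g}" if isinstance(x, float) else str(x)


def write_fixture(truth: GroundTruth, frames: Sequence[FrameImage],
                  out_dir: str | Path, overwrite: bool = False) -> Path:
    """Write numbered PNG frames, a matched config file and ground-truth CSVs.

    Re-running with the same spec (same seed) reproduces the files byte for
    byte.  Refuses to write into a non-empty directory unless ``overwrite``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} is not empty (pass overwrite=True)")
    for fr in frames:
        iio.imwrite(out / f"frame_{fr.index:06d}.png", fr.pixels)
    truth.trial_config().save(out / "config.yaml")

    with open(out / "truth_schedule.csv", "w", newline="") as fh:
        fh.write("leg,onset_frame,offset_frame,aep_x_px,aep_y_px,"
                 "pep_x_px,pep_y_px\n")
        for st in sorted(truth.stances, key=lambda s: (s.onset, s.leg.value)):
            fh.write(",".join([st.leg.value, str(st.onset), str(st.offset),
                               _fmt(float(st.anchor_path[0, 0])),
                               _fmt(float(st.anchor_path[0, 1])),
                               _fmt(float(st.anchor_path[-1, 0])),
                               _fmt(float(st.anchor_path[-1, 1]))]) + "\n")
    with open(out / "truth_poses.csv", "w", newline="") as fh:
        fh.write("frame,center_x_px,center_y_px,orientation_rad\n")
        for f in range(truth.n_frames):
            fh.write(f"{f},{_fmt(float(truth.center_x[f]))},"
                     f"{_fmt(truth.center_y)},0\n")
    with open(out / "truth_params.csv", "w", newline="") as fh:
        fh.write("parameter,value\n")
        for k, v in [("duty_factor", truth.duty_true),
                     ("stride_mm", truth.stride_mm_true),
                     ("speed_avg_cm_s", truth.speed_avg_true),
                     ("phase_fore", truth.phase_fore_true),
                     ("phase_hind", truth.phase_hind_true),
                     ("period_frames", truth.period_frames),
                     ("stance_frames", truth.stance_frames)]:
            fh.write(f"{k},{_fmt(float(v))}\n")
    return out


def load_spec(path: str | Path) -> SyntheticGaitSpec:
    """Read a SyntheticGaitSpec from a YAML key-value file."""
    import yaml
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(SyntheticGaitSpec)}
    unknown = set(d) - known
    if unknown:
        raise KeyError(f"unknown spec keys: {sorted(unknown)}")
    return SyntheticGaitSpec(**d)
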