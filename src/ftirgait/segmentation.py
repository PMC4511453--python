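"""Frame segmentation: background model, pixel classes, body pose, footprints.

The fTIR walkway is imaged from below: the body silhouette appears at an
intermediate intensity while paw-floor contacts scatter the internally
reflected light and appear as bright spots.  Segmentation therefore runs in
three steps per frame: (1) subtract a per-pixel median background model,
(2) classify the remaining pixels as footprint or body by per-channel
intensity ranges (footprint rule wins ties), and (3) decompose the body
mask into nose, head, center, back point and tail landmarks.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .config import TrialConfig

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class FrameImage:
    """One video frame: ``pixels`` is H×W (grayscale) or H×W×3 uint8."""

    index: int
    time: float
    pixels: np.ndarray

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]

    def channels(self) -> np.ndarray:
        """Pixels as float H×W×C regardless of input layout."""
        px = self.pixels.astype(np.float64)
        return px[..., None] if px.ndim == 2 else px


@dataclass
class BackgroundModel:
    """Per-pixel, per-channel median of the animal-free frames."""

    median_color: np.ndarray          # H×W×C float
    tolerance: np.ndarray             # per-channel, length C
    never_excluded: np.ndarray | None = None  # H×W bool, pixels that fell back
                                              # to the global median


@dataclass
class PixelMasks:
    """Disjoint, exhaustive partition of one frame's pixels."""

    body: np.ndarray
    footprint: np.ndarray
    background: np.ndarray


@dataclass
class BodyPose:
    frame: int
    nose: tuple[float, float]
    head_center: tuple[float, float]
    head_direction: tuple[float, float]
    body_center: tuple[float, float]
    body_orientation: float           # radians, major axis toward the nose
    back_point: tuple[float, float]
    back_direction: tuple[float, float]
    tail_base: tuple[float, float] | None
    tail_points: list[tuple[float, float]] = field(default_factory=list)
    tail_orientations: list[float] = field(default_factory=list)
    body_length: float = 0.0          # cm, nose to tail base
    flags: list[str] = field(default_factory=list)


@dataclass
class FootprintBlob:
    frame: int
    pixel_coords: np.ndarray          # N×2 array of (x, y)
    centroid: tuple[float, float]     # brightness-weighted (x, y)
    area_px: int
    brightness_sum: float


# ---------------------------------------------------------------------------
# frame loading
# ---------------------------------------------------------------------------

_FRAME_RE = re.compile(r"(\d+)\.(png|tif|tiff)$", re.IGNORECASE)


def load_frames(frames_dir: str | Path, frame_rate_hz: float) -> list[FrameImage]:
    """Load numbered PNG/TIFF frames from a directory, or a multi-page TIFF.

    Files are ordered by the trailing number in their name; the timestamps
    come from ``frame_rate_hz`` (never inferred from the data).
    """
    path = Path(frames_dir)
    if path.is_file():
        stack = iio.imread(path)
        if stack.ndim == 2 or (stack.ndim == 3 and stack.shape[2] in (1, 3)):
            stack = stack[None]
        return [FrameImage(i, i / frame_rate_hz, np.asarray(fr))
                for i, fr in enumerate(stack)]
    entries = []
    for p in sorted(path.iterdir()):
        m = _FRAME_RE.search(p.name)
        if m:
            entries.append((int(m.group(1)), p))
    if not entries:
        raise FileNotFoundError(f"no numbered PNG/TIFF frames in {path}")
    entries.sort()
    frames = []
    shape = None
    for i, (_, p) in enumerate(entries):
        px = np.asarray(iio.imread(p))
        if px.ndim == 3 and px.shape[2] == 4:   # drop alpha
            px = px[:, :, :3]
        if shape is None:
            shape = px.shape
        elif px.shape != shape:
            raise ValueError(f"frame {p.name} shape {px.shape} != {shape}")
        frames.append(FrameImage(i, i / frame_rate_hz, px))
    return frames


# ---------------------------------------------------------------------------
# background model
# ---------------------------------------------------------------------------


def build_background(
    frames: Sequence[FrameImage],
    exclusion_masks: Optional[Sequence[np.ndarray]] = None,
    tolerance: Sequence[float] | float = 12.0,
) -> BackgroundModel:
    """Per-pixel, per-channel median over frames where the pixel is animal-free.

    With explicit ``exclusion_masks`` (True = animal present) the median at
    each pixel uses only frames where that pixel is not excluded; a pixel
    excluded in every frame receives the global median and is flagged.
    Without masks, all frames contribute at every pixel.
    """
    if len(frames) == 0:
        raise ValueError("no frames")
    if len(frames) < 3:
        raise ValueError("need at least 3 frames to build a background")
    shape = frames[0].pixels.shape
    for f in frames:
        if f.pixels.shape != shape:
            raise ValueError("frames have mismatched dimensions")
    stack = np.stack([f.channels() for f in frames])       # N×H×W×C
    tol = np.atleast_1d(np.asarray(tolerance, dtype=float))
    if tol.size == 1:
        tol = np.repeat(tol, stack.shape[3])
    if exclusion_masks is None:
        med = np.median(stack, axis=0)
        return BackgroundModel(med, tol)
    excl = np.stack([np.asarray(m, dtype=bool) for m in exclusion_masks])
    if excl.shape != stack.shape[:3]:
        raise ValueError("exclusion masks do not match frame dimensions")
    masked = np.ma.masked_array(stack, mask=np.broadcast_to(
        excl[..., None], stack.shape))
    med = np.ma.median(masked, axis=0)
    always = excl.all(axis=0)                              # H×W
    global_med = np.median(stack.reshape(-1, stack.shape[3]), axis=0)
    med = med.filled(0.0)
    med[always] = global_med
    return BackgroundModel(med, tol, never_excluded=always)


def build_background_two_pass(
    frames: Sequence[FrameImage], cfg: TrialConfig
) -> BackgroundModel:
    """Bootstrap animal-presence masks, then take the animal-free median.

    On an fTIR walkway the floor is the darkest stable state of every
    pixel: the body silhouette and the scattered contact light only ever
    add brightness.  Pass 1 therefore takes a per-pixel low percentile of
    the brightness as the floor reference; frames brighter than it by more
    than the background tolerance are flagged as animal-present.  Pass 2
    is the per-pixel median over the remaining animal-free frames.  The
    one-sided bootstrap stays valid even when the animal (body plus
    trailing tail) dwells over a pixel for most of the recording, where a
    median-based bootstrap would lock onto the animal.
    """
    bright = np.stack([f.channels().mean(axis=2) for f in frames])
    floor = np.percentile(bright, 25, axis=0)
    tol = float(np.mean(cfg.bg_tolerance))
    masks = [b > floor + tol for b in bright]
    return build_background(frames, exclusion_masks=masks,
                            tolerance=cfg.bg_tolerance)


# ---------------------------------------------------------------------------
# pixel classification
# ---------------------------------------------------------------------------


def classify_pixels(frame: FrameImage, bg: BackgroundModel,
                    cfg: TrialConfig) -> PixelMasks:
    """Partition a frame into background / footprint / body masks.

    A pixel within the background tolerance of its median is background.
    Otherwise the footprint per-channel range is tested first (footprints
    may overlap the body silhouette when viewed from below), then the body
    range; anything matching neither falls back to background, keeping the
    partition exhaustive.
    """
    px = frame.channels()
    if px.shape[:2] != bg.median_color.shape[:2]:
        raise ValueError("frame dimensions do not match background model")
    nc = px.shape[2]
    is_bg = (np.abs(px - bg.median_color) <= bg.tolerance[:nc]).all(axis=2)
    fp_lo = np.asarray(cfg.footprint_rgb_min[:nc])
    fp_hi = np.asarray(cfg.footprint_rgb_max[:nc])
    bd_lo = np.asarray(cfg.body_rgb_min[:nc])
    bd_hi = np.asarray(cfg.body_rgb_max[:nc])
    is_fp = ((px >= fp_lo) & (px <= fp_hi)).all(axis=2) & ~is_bg
    is_body = ((px >= bd_lo) & (px <= bd_hi)).all(axis=2) & ~is_bg & ~is_fp
    background = ~(is_fp | is_body)
    return PixelMasks(body=is_body, footprint=is_fp, background=background)


# ---------------------------------------------------------------------------
# body decomposition
# ---------------------------------------------------------------------------


def _principal_angle(xs: np.ndarray, ys: np.ndarray) -> float:
    """Major-axis angle of a point set from second central moments."""
    mx, my = xs.mean(), ys.mean()
    dx, dy = xs - mx, ys - my
    mu20, mu02, mu11 = (dx * dx).mean(), (dy * dy).mean(), (dx * dy).mean()
    return 0.5 * np.arctan2(2.0 * mu11, mu20 - mu02)


def _wrap(a: float) -> float:
    return float((a + np.pi) % (2.0 * np.pi) - np.pi)


def decompose_body(
    masks: PixelMasks,
    cfg: TrialConfig,
    frame_index: int = 0,
    prev: Optional[Sequence[BodyPose]] = None,
) -> Optional[BodyPose]:
    """Split the body mask into tail and tail-less body and locate landmarks.

    The tail is the maximal run of thin cross-sections (width below
    ``tail_thickness_frac`` of the maximum body width) starting from one
    extremity of the body's principal axis.  Returns None (frame untracked)
    when no body component of at least ``min_body_area`` pixels exists.

    ``prev`` may carry recent poses; their body-center displacement breaks
    the nose/tail symmetry when the silhouette has no tail.
    """
    lab, n = ndimage.label(masks.body, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return None
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < cfg.min_body_area:
        return None
    ys, xs = np.nonzero(lab == best)
    xs = xs.astype(np.float64)
    ys = ys.astype(np.float64)

    theta0 = _principal_angle(xs, ys)
    c, s = np.cos(theta0), np.sin(theta0)
    cx, cy = xs.mean(), ys.mean()
    along = (xs - cx) * c + (ys - cy) * s        # axis coordinate
    perp = -(xs - cx) * s + (ys - cy) * c

    # 1-px bins along the principal axis; per-bin cross-section width
    bins = np.floor(along - along.min()).astype(int)
    nbins = bins.max() + 1
    width = np.full(nbins, 0.0)
    for b in range(nbins):
        sel = bins == b
        if sel.any():
            width[b] = perp[sel].max() - perp[sel].min() + 1.0
    occupied = width > 0
    thr = cfg.tail_thickness_frac * width[occupied].max()

    def run_from(idx_order: np.ndarray) -> int:
        k = 0
        for b in idx_order:
            if not occupied[b]:
                continue
            if width[b] < thr:
                k += 1
            else:
                break
        return k

    lo_run = run_from(np.arange(nbins))
    hi_run = run_from(np.arange(nbins)[::-1])
    min_bins = max(3, int(cfg.min_tail_frac * nbins))
    flags: list[str] = []

    tail_sel = np.zeros(xs.shape[0], dtype=bool)
    has_tail = False
    if lo_run >= min_bins or hi_run >= min_bins:
        has_tail = True
        if lo_run >= min_bins and hi_run >= min_bins:
            flags.append("ambiguous_tail")
        if lo_run >= hi_run and lo_run >= min_bins:
            tail_bins = np.arange(lo_run)
            tail_from_low = True
        else:
            tail_bins = np.arange(nbins - hi_run, nbins)
            tail_from_low = False
        tail_sel = np.isin(bins, tail_bins)

    tail_base = None
    tail_points: list[tuple[float, float]] = []
    tail_orients: list[float] = []
    if has_tail:
        # per-bin centroid polyline, ordered base -> tip
        poly = []
        seq = tail_bins[::-1] if tail_from_low else tail_bins
        for b in seq:
            sel = bins == b
            if sel.any():
                poly.append((xs[sel].mean(), ys[sel].mean()))
        poly = np.asarray(poly)                   # base -> tip
        tail_base = (float(poly[0, 0]), float(poly[0, 1]))
        if len(poly) >= 2:
            seg = np.diff(poly, axis=0)
            arclen = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
            total = arclen[-1]
            for frac in (0.25, 0.5, 0.75):
                t = frac * total
                j = int(np.searchsorted(arclen, t, side="right") - 1)
                j = min(j, len(poly) - 2)
                u = 0.0 if arclen[j + 1] == arclen[j] else \
                    (t - arclen[j]) / (arclen[j + 1] - arclen[j])
                pt = poly[j] * (1 - u) + poly[j + 1] * u
                tail_points.append((float(pt[0]), float(pt[1])))
                # local direction oriented base-ward, so a straight tail
                # reads the same angle as the body axis
                d = poly[j] - poly[j + 1]
                tail_orients.append(float(np.arctan2(d[1], d[0])))

    body_sel = ~tail_sel
    bx, by = xs[body_sel], ys[body_sel]
    body_center = (float(bx.mean()), float(by.mean()))
    theta = _principal_angle(bx, by)

    # nose: tail-less extremity farthest from the tail base (or travel dir)
    if tail_base is not None:
        d2 = (bx - tail_base[0]) ** 2 + (by - tail_base[1]) ** 2
        ni = int(np.argmax(d2))
        nose = (float(bx[ni]), float(by[ni]))
    else:
        flags.append("no_tail")
        axis = np.array([np.cos(theta), np.sin(theta)])
        proj = (bx - body_center[0]) * axis[0] + (by - body_center[1]) * axis[1]
        direction = 1.0
        if prev:
            recent = [p.body_center for p in prev[-5:]]
            if len(recent) >= 2:
                disp = np.subtract(recent[-1], recent[0])
                if np.dot(disp, axis) < 0:
                    direction = -1.0
        ni = int(np.argmax(direction * proj))
        nose = (float(bx[ni]), float(by[ni]))

    # orient the major axis toward the nose
    axis = np.array([np.cos(theta), np.sin(theta)])
    to_nose = np.array(nose) - np.array(body_center)
    if np.dot(axis, to_nose) < 0:
        theta = _wrap(theta + np.pi)

    # head: body pixels within the head distance of the nose
    if tail_base is not None:
        body_len_px = float(np.hypot(nose[0] - tail_base[0], nose[1] - tail_base[1]))
    else:
        proj = (bx - body_center[0]) * np.cos(theta) + \
               (by - body_center[1]) * np.sin(theta)
        body_len_px = float(proj.max() - proj.min())
    head_r = cfg.head_distance_frac * body_len_px
    hd2 = (bx - nose[0]) ** 2 + (by - nose[1]) ** 2
    hsel = hd2 <= head_r * head_r
    if hsel.sum() >= 3:
        head_center = (float(bx[hsel].mean()), float(by[hsel].mean()))
        ha = _principal_angle(bx[hsel], by[hsel])
        hv = np.array([np.cos(ha), np.sin(ha)])
        to_nose_h = np.array(nose) - np.array(head_center)
        nrm = np.linalg.norm(to_nose_h)
        if nrm > 1e-9 and np.dot(hv, to_nose_h) < 0:
            hv = -hv
        elif nrm <= 1e-9:
            hv = np.array([np.cos(theta), np.sin(theta)])
        head_dir = (float(hv[0]), float(hv[1]))
    else:
        head_center = nose
        head_dir = (float(np.cos(theta)), float(np.sin(theta)))

    if tail_base is not None:
        back_point = ((body_center[0] + tail_base[0]) / 2.0,
                      (body_center[1] + tail_base[1]) / 2.0)
        bv = np.array(body_center) - np.array(tail_base)
        bn = np.linalg.norm(bv)
        back_dir = (float(bv[0] / bn), float(bv[1] / bn)) if bn > 1e-9 else \
            (float(np.cos(theta)), float(np.sin(theta)))
    else:
        back_point = body_center
        back_dir = (float(np.cos(theta)), float(np.sin(theta)))

    return BodyPose(
        frame=frame_index,
        nose=nose,
        head_center=head_center,
        head_direction=head_dir,
        body_center=body_center,
        body_orientation=float(theta),
        back_point=back_point,
        back_direction=back_dir,
        tail_base=tail_base,
        tail_points=tail_points,
        tail_orientations=tail_orients,
        body_length=body_len_px / cfg.px_per_cm,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# footprint extraction
# ---------------------------------------------------------------------------


def extract_footprints(masks: PixelMasks, frame: FrameImage,
                       cfg: TrialConfig) -> list[FootprintBlob]:
    """8-connected footprint blobs with brightness-weighted centroids.

    Brightness is the mean over channels; blobs below ``min_blob_area``
    pixels are dropped as fTIR flicker.
    """
    lab, n = ndimage.label(masks.footprint, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return []
    brightness = frame.channels().mean(axis=2)
    blobs: list[FootprintBlob] = []
    for i in range(1, n + 1):
        sel = lab == i
        area = int(sel.sum())
        if area < cfg.min_blob_area:
            continue
        ys, xs = np.nonzero(sel)
        w = brightness[ys, xs]
        wsum = float(w.sum())
        cxw = float((xs * w).sum() / wsum)
        cyw = float((ys * w).sum() / wsum)
        blobs.append(FootprintBlob(
            frame=frame.index,
            pixel_coords=np.column_stack([xs, ys]),
            centroid=(cxw, cyw),
            area_px=area,
            brightness_sum=wsum,
        ))
    return blobs
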