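# Methods

`ftirgait` estimates gait parameters from bottom-view video of a rodent
crossing a frustrated-total-internal-reflection (fTIR) walkway.  This note
documents the model behind each stage, the tunable parameters and their
defaults, what the synthetic generator does and does not emulate, the
numerical choices, and known limitations.

## Imaging model and segmentation

The walkway floor is the darkest stable state of every pixel; the body
silhouette appears at intermediate brightness and paw contacts as bright
spots whose intensity scales with the applied pressure.  All geometry uses
image pixel coordinates (0-based, origin top-left, x along the walkway,
y downward) until footprints are transformed into the body frame.

**Background model.**  The background is the per-pixel, per-channel median
over the frames in which the animal is absent at that pixel.  Absence is
bootstrapped from fTIR physics: pass 1 takes a per-pixel 25th percentile of
brightness as the floor reference (the animal only ever *adds* light, so a
low percentile is robust even when body or tail dwell over a pixel for most
of the recording — which they do on the walkway centerline whenever the
trial is not much longer than the animal); frames brighter than that
reference by more than `bg_tolerance` (default 12 intensity units per
channel) are marked animal-present; pass 2 is the median over the
remaining frames.  A median-referenced bootstrap was tried first and
demonstrably locks onto the animal along the tail line once the animal
covers a pixel for ≥50 % of frames; the percentile reference is the
package's fix.  Pixels excluded in every frame fall back to the global
median and are flagged.  The bootstrap assumes each pixel is animal-free in
at least ~25 % of frames.

**Pixel classes.**  A pixel within `bg_tolerance` of its median is
background; otherwise the footprint per-channel range
(`footprint_rgb_min/max`, default 170–255) is tested before the body range
(`body_rgb_min/max`, default 60–160), because contacts are seen through
the floor and overlap the silhouette; anything matching neither reverts to
background.  The three masks always partition the frame.  Grayscale input
uses the single-channel ranges; color input allows independent per-channel
thresholds (e.g. body in red, contacts in green).  Footprint pixels are
*excluded* from the body mask — a deliberate interpretation that keeps the
partition disjoint; the pose moments are insensitive to the resulting
small holes (≲0.5 px shift on the synthetic trials).

**Body decomposition.**  Cross-section widths are measured perpendicular
to the principal axis of the full body component in 1-px bins of axis
position.  The tail is the maximal run of bins whose width is below
`tail_thickness_frac` (default 0.25) of the maximum width, starting from an
extremity; a run must span at least `min_tail_frac` (default 0.10) of the
axis extent to count as a tail, which distinguishes a true tail from the
natural taper of an ellipse tip (both tips of a tail-less body are thin,
but only briefly).  If both extremities carry qualifying runs the longer
wins and the pose is flagged ambiguous.  The tail base is the first bin at
or above the threshold; three tail points sit at 1/4, 1/2 and 3/4 of the
tail arc length with local directions oriented base-ward, so a straight
tail reads the same angle as the body axis.  The nose is the tail-less
pixel farthest from the tail base (for tail-less bodies: the extremity in
the direction of recent body-center travel, from up to 5 previous poses).
Body center and orientation are the centroid and second-central-moment
major axis of the tail-less body, sign-disambiguated toward the nose; the
head is the body within `head_distance_frac` (default 0.25) of the nose
× body length; the back point is the midpoint of body center and tail
base.  Body length is the nose–tail-base distance (cm via `px_per_cm`).

**Footprints.**  8-connected components of the footprint mask with at
least `min_blob_area` px (default 4) become blobs with brightness-weighted
centroids (brightness = channel mean); `min_body_area` (default 200 px)
suppresses spurious body components.

## Tracking

Stance footprints are anchored to the floor, so linking is greedy
nearest-centroid, frame order, with two gates: an absolute search radius
`max_link_dist_px` (20 px) and a per-elapsed-frame drift bound
`max_stance_drift_px` (5 px/frame).  The drift bound is what separates a
hind-paw touchdown from the forepaw print it lands next to one frame after
liftoff — without it the two merge at higher speeds.  Dropouts up to
`max_gap_frames` (2) are bridged with linearly interpolated centroids
(zero area/brightness on bridged frames); tracks shorter than
`min_stance_frames` (3 frames, 12 ms at 250 Hz) are discarded as flicker.

Leg identity is read from the event's mean centroid in the body frame at
stance onset: lateral > 0 is the animal's left (the view is from below;
with image y down, the left side lies at +90° from the heading);
longitudinal ≥ `fore_hind_split` (0, the body center) is fore.  Within a
±0.02 body-length dead zone the label is inherited from the spatially
nearest preceding event on a candidate leg, else flagged ambiguous.

Step cycles are stance-onset to stance-onset per leg: stance time from the
first event, swing time the gap to the next onset, period their sum
(exact, in integer frames), step length the centroid-to-centroid distance
in mm.

## Kinematics

Instantaneous speed is the central-difference velocity magnitude of the
body center, converted to cm/s and smoothed with a centered moving average
of `speed_smooth_win` (5) frames; gaps up to 10 frames are interpolated,
longer gaps are an error.  Average speed is net displacement over elapsed
time (the animal is assumed to progress along the walkway).  Duty factor
is stance/period per cycle; the per-trial value is the flat mean over all
legs' cycles (pooling cycles, not legs first — the aggregation is a
package choice).  A trial with mean duty ≥ 0.5 is a walk, else a run.
Across trials, ordinary least squares of duty on speed gives the
walk-to-run crossing speed (0.5 − intercept)/slope, defined only for
negative slopes (slopes ≥ −1e−12 are flagged).  An optional
a·exp(−b·v)+c fit describes stance time versus speed; its coefficients are
reported, never asserted.

## Coordination

Footprint positions are expressed in the body frame — translate by the
body center, rotate by the orientation, divide by body length — giving
longitudinal (+ anterior) and lateral (+ left) coordinates in body-length
units.  A stance trace is the per-frame body-frame trajectory of one
event's centroids (poses interpolated where missing, with unwrapped-angle
interpolation; traces with <80 % tracked poses are flagged and excluded
from aggregates).  Its first and last points are the AEP and PEP.

- **Footprint clustering** is, per leg with ≥2 steps, the standard
  distance √(var long + var lat) of the chosen endpoint across steps
  (population variances), averaged over qualifying legs.  The 2-D standard
  distance per video is the interpretation that matches one value per
  trial; the alternative reading (SD of per-video averages) would need
  many videos.
- **Stance linearity** is the mean Euclidean deviation of a trace from its
  centered moving average (`linearity_smooth_win`, default 15 frames =
  60 ms at 250 Hz, shrunk symmetrically at the ends so straight uniform
  traces score exactly 0).  Traces shorter than the window are undefined;
  at speeds where every stance is shorter, the per-trial value is reported
  as undefined rather than computed with a smaller window.  The body
  linearity index applies the same formula to the body-center path, in mm.
- **Leg combinations.**  Each frame's stance flags (taken from gap-filled
  stance-event intervals, not raw blob detections, to avoid flicker) map
  to one of seven swing categories: none, single, diagonal ({LF,RH} or
  {RF,LH}), lateral ({LF,LH} or {RF,RH}), front-or-hind ({LF,RF} or
  {LH,RH}), three-leg, all-legs — a total map over the 16 combinations
  (1/4/2/2/2/4/1 states respectively).  Indexes are fractions of
  classified frames (frames without a tracked pose are excluded from the
  denominator) and sum to 1.
- **Contralateral phase.**  For each reference-leg cycle [t_i, t_{i+1}),
  the partner leg's onset inside it yields phase (t_p − t_i)/(t_{i+1} −
  t_i); onset-based phases were chosen over whole-cycle cross-correlation
  for robustness to stance-shape differences.  Means and dispersions are
  circular (angles 2πφ; dispersion √(−2 ln R)/2π), which is exact at the
  0/1 wrap where a linear mean fails; near 0.5 the two agree.
- **Tail metrics** report each tail segment's orientation minus the body
  orientation, proximal/distal minus middle, and the middle tail point's
  frame-to-frame displacement projected on the body-frame lateral axis
  (cm/s).
- **Pressure series** report per-frame footprint area (cm²), summed
  brightness, and brightness per pixel — a relative pressure readout; no
  absolute calibration is attempted.

## Synthetic trials

The generator emulates the measurement, not the biomechanics: a rigid
ellipse body (default 7 × 2.5 cm) with a tapered 6 cm tail glides at
constant speed (optionally sinusoidally modulated at the stride frequency)
over a dark floor (level 20), rendered at 250 Hz and 10 px/cm with
additive Gaussian pixel noise (σ = 2).  Paw contacts are flat-topped
(super-Gaussian) bright spots (peak 235 over background, width 0.25 cm)
anchored to the floor for the whole stance; their amplitude ramps over the
first 10 % of stance and a toe sub-spot 0.3 cm anterior grows over the
last third, shifting the brightness centroid rostrally as weight moves
onto the toes before liftoff.  Touchdown positions get isotropic jitter
(`aep_jitter_cm`, default 0.05); an optional slip term drifts the anchor
by N(0, `pep_jitter_cm`) over the stance, the mechanism by which liftoff
positions scatter more than touchdowns.

The stance schedule follows a per-leg phase table (trot: diagonal pairs in
sync, contralateral offset `pair_phase` = 0.5; pace patterning via
`diagonal=False`; arbitrary tables via `phase_offsets`), with the period
rounded to whole frames and the stance to round(duty × period).  All
"true" values (duty, stride, average speed, phases) are recorded from the
integer-frame schedule actually emitted, so recovery scores measure the
pipeline, not quantization.  Defaults describe a mouse trotting at
30 cm/s with 30 mm strides and duty 0.55 — typical of walkway crossings —
and 8 cycles.  The end-to-end validation grid uses 15/30/45/60 cm/s with
strides of 30/30/36/36 mm (strides lengthen with speed in real mice; these
values also make the period a whole number of frames) and 12 cycles per
trial (~240–630 frames), sizes chosen to exercise every stage at full
fidelity while keeping the suite fast.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: non-rigid body deformation, fur texture
and shadowing, toe morphology (spots are radially symmetric), crossing or
merging footprints (hind prints land *near*, not on, previous fore
prints), curved walking paths, grooming/rearing pauses, and illumination
inhomogeneity beyond per-pixel offsets absorbed by the median model.

## Numerical choices and degenerate inputs

CSV floats are written with 6 significant digits, making re-runs
byte-identical; missing values are the explicit marker `undefined` plus a
reason column in the summary.  Ties in nose selection fall to the first
pixel in scan order (mirror tests therefore allow 1.5 px).  Empty frame
sets, <3 background frames, mismatched dimensions, thresholds outside
[0, 255], overlapping same-leg events, zero classified frames and
non-positive body lengths all raise; a missing body component flags the
frame untracked rather than raising.  Seeded generators
(`numpy.random.default_rng` with per-purpose SeedSequence keys) make every
synthetic artifact reproducible from a single integer seed.

## Known limitations

- Greedy linking cannot re-identify a footprint after occlusions longer
  than `max_gap_frames`, and merged fore/hind blobs stay merged (flagged
  ambiguous at identification rather than split).
- The background bootstrap assumes the animal brightens pixels; a dark
  animal on a bright floor would need inverted thresholds.
- Leg identification assumes a single animal walking roughly parallel to
  its body axis; sharp turns could swap fore/hind labels near the split.
- Stance linearity is undefined at speeds where every stance is shorter
  than the smoothing window (e.g. <60 ms stances at the default window).
- Pressure is relative; converting to force would require a calibration
  recording, which the package does not model.
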