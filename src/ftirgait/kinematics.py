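"""Speed and step-parameter kinematics: duty factor, gait regime, regressions.

The duty factor (stance duration / period) separates walking from running:
values at or above 0.5 are walks, below 0.5 runs.  Across trials the duty
factor falls roughly linearly with speed; the fitted line's crossing of 0.5
estimates the walk-to-run transition speed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .config import TrialConfig
from .segmentation import BodyPose
from .tracking import StepCycle


@dataclass
class SpeedSeries:
    frames: np.ndarray          # frame numbers within the valid range
    instantaneous: np.ndarray   # cm/s, same length as frames
    average: float              # cm/s, net displacement / elapsed time
    valid_range: tuple[int, int]


@dataclass
class DutyRegression:
    slope: float                # per (cm/s)
    intercept: float            # dimensionless
    crossing_speed: Optional[float]   # cm/s where fitted duty = 0.5
    flagged: bool = False       # slope >= 0: no walk-to-run crossing


def _moving_average(v: np.ndarray, win: int) -> np.ndarray:
    """Centered moving average, window shrunk symmetrically at the ends."""
    n = len(v)
    out = np.empty(n)
    half = win // 2
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = v[i - h:i + h + 1].mean()
    return out


def instantaneous_speed(poses: Mapping[int, BodyPose],
                        cfg: TrialConfig) -> SpeedSeries:
    """Central-difference speed of the body center, smoothed and in cm/s.

    Untracked frames inside the valid range are linearly interpolated when
    the gap is at most 10 frames; longer gaps raise.  The average speed is
    the net body-center displacement over the elapsed time (animals are
    assumed to progress along the walkway, not wander).
    """
    if len(poses) < 3:
        raise ValueError("need at least 3 tracked poses")
    frames = np.array(sorted(poses))
    gaps = np.diff(frames)
    if (gaps > 10 + 1).any():
        raise ValueError(
            f"untracked gap of {int(gaps.max()) - 1} frames exceeds 10")
    full = np.arange(frames[0], frames[-1] + 1)
    cx = np.interp(full, frames, [poses[int(f)].body_center[0] for f in frames])
    cy = np.interp(full, frames, [poses[int(f)].body_center[1] for f in frames])
    vx = np.gradient(cx)        # px/frame, central differences
    vy = np.gradient(cy)
    speed = np.hypot(vx, vy) * cfg.frame_rate_hz / cfg.px_per_cm
    speed = _moving_average(speed, cfg.speed_smooth_win)
    net = np.hypot(cx[-1] - cx[0], cy[-1] - cy[0]) / cfg.px_per_cm
    elapsed = (full[-1] - full[0]) / cfg.frame_rate_hz
    return SpeedSeries(frames=full, instantaneous=speed,
                       average=float(net / elapsed),
                       valid_range=(int(full[0]), int(full[-1])))


def duty_factor(cycle: StepCycle) -> float:
    """Fraction of the step cycle spent in stance; 1.0 flags a missing swing."""
    if cycle.period <= 0:
        raise ValueError("cycle period must be positive")
    return cycle.stance_time / cycle.period


def swing_speed(cycle: StepCycle) -> Optional[float]:
    """Average foot speed during swing, m/s; None when no swing was seen."""
    if cycle.swing_time <= 0:
        return None
    return (cycle.step_length / 1000.0) / cycle.swing_time


def classify_gait_regime(mean_duty: float) -> str:
    """'walk' for duty factor >= 0.5, 'run' below (boundary inclusive)."""
    if not 0.0 <= mean_duty <= 1.0:
        raise ValueError("mean duty factor must lie in [0, 1]")
    return "walk" if mean_duty >= 0.5 else "run"


def fit_duty_speed_regression(
        trials: Sequence[tuple[float, float]]) -> DutyRegression:
    """OLS of per-trial mean duty factor on average speed.

    The walk-to-run crossing speed solves fitted duty = 0.5, i.e.
    (0.5 - intercept) / slope; undefined (flagged) for non-negative slope.
    """
    if len(trials) < 3:
        raise ValueError("need at least 3 trials")
    v = np.array([t[0] for t in trials], dtype=float)
    d = np.array([t[1] for t in trials], dtype=float)
    if v.max() - v.min() <= 10.0:
        raise ValueError("trials must span more than 10 cm/s")
    slope, intercept = np.polyfit(v, d, 1)
    if slope >= -1e-12:     # flat or rising: no walk-to-run crossing
        return DutyRegression(float(slope), float(intercept), None, flagged=True)
    crossing = (0.5 - intercept) / slope
    return DutyRegression(float(slope), float(intercept), float(crossing))


def crossing_speed_from_coefficients(slope: float, intercept: float) -> float:
    """Speed at which a given duty-vs-speed line crosses duty = 0.5."""
    if slope >= 0:
        raise ValueError("no walk-to-run crossing for non-negative slope")
    return (0.5 - intercept) / slope


def mean_trial_duty(cycles: Sequence[StepCycle]) -> Optional[float]:
    """Per-trial duty factor: flat mean over all legs' cycle-level values."""
    vals = [duty_factor(c) for c in cycles if c.period > 0]
    return float(np.mean(vals)) if vals else None


def fit_stance_time_exponential(
        trials: Sequence[tuple[float, float]]) -> Optional[tuple[float, float, float]]:
    """Optional a*exp(-b*v)+c fit of stance time vs speed; None on failure.

    Stance durations shorten steeply with speed toward an asymptote; the
    coefficients are reported descriptively, not asserted.
    """
    if len(trials) < 4:
        return None
    v = np.array([t[0] for t in trials], dtype=float)
    s = np.array([t[1] for t in trials], dtype=float)
    try:
        popt, _ = curve_fit(
            lambda x, a, b, c: a * np.exp(-b * x) + c, v, s,
            p0=(s.max() - s.min() + 1e-3, 0.05, max(s.min(), 1e-4)),
            maxfev=5000)
    except RuntimeError:
        return None
    return tuple(float(x) for x in popt)
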