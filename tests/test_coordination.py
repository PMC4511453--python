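"""Body-frame geometry, stance traces, clustering, combinations, phases."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import ftirgait as fg
from ftirgait import coordination as coord

from conftest import make_pose

CFG = fg.TrialConfig()


class TestBodyFrame:
    def test_body_center_maps_to_origin(self):
        pose = make_pose(center=(120.0, 40.0), orientation=0.3)
        p = fg.to_body_frame((120.0, 40.0), pose, CFG.px_per_cm)
        assert (p.longitudinal, p.lateral) == (0.0, 0.0)

    def test_one_body_length_ahead(self):
        pose = make_pose(center=(100.0, 50.0), orientation=0.0)
        bl_px = pose.body_length * CFG.px_per_cm
        p = fg.to_body_frame((100.0 + bl_px, 50.0), pose, CFG.px_per_cm)
        assert p.longitudinal == pytest.approx(1.0)
        assert p.lateral == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(-200, 200), st.floats(-200, 200),
           st.floats(-np.pi, np.pi), st.floats(1.0, 15.0))
    def test_round_trip_identity(self, x, y, theta, bl):
        pose = make_pose(center=(100.0, 50.0), orientation=theta,
                         body_length=bl)
        p = fg.to_body_frame((x, y), pose, CFG.px_per_cm)
        back = fg.from_body_frame(p, pose, CFG.px_per_cm)
        np.testing.assert_allclose(back, (x, y), atol=1e-9 * bl * CFG.px_per_cm)

    def test_zero_body_length_rejected(self):
        pose = make_pose(body_length=0.0)
        with pytest.raises(ValueError):
            fg.to_body_frame((1.0, 2.0), pose, CFG.px_per_cm)


def _event(onset, n, xy):
    return fg.StanceEvent(onset_frame=onset, offset_frame=onset + n - 1,
                          centroids=np.tile(np.asarray(xy, float), (n, 1)),
                          areas=np.full(n, 25),
                          brightness=np.full(n, 2500.0))


class TestStanceTrace:
    def test_advancing_body_over_fixed_foot_is_straight_line(self):
        poses = {f: make_pose(frame=f, center=(100.0 + 2.0 * f, 50.0))
                 for f in range(20)}
        ev = _event(0, 20, (130.0, 43.0))
        tr = fg.build_stance_trace(ev, poses, CFG)
        assert not tr.flagged
        assert np.all(np.diff(tr.points[:, 0]) < 0)       # slides caudally
        np.testing.assert_allclose(tr.points[:, 1], tr.points[0, 1],
                                   atol=1e-12)
        assert tr.aep.longitudinal == pytest.approx(tr.points[0, 0])
        assert tr.pep.longitudinal == pytest.approx(tr.points[-1, 0])

    def test_zero_body_motion_collapses_to_point(self):
        poses = {f: make_pose(frame=f, center=(100.0, 50.0))
                 for f in range(10)}
        tr = fg.build_stance_trace(_event(0, 10, (120.0, 45.0)), poses, CFG)
        assert np.ptp(tr.points, axis=0).max() < 1e-12

    def test_sparse_poses_flag_trace(self):
        poses = {f: make_pose(frame=f, center=(100.0, 50.0))
                 for f in range(0, 10, 5)}                 # 2 of 10 tracked
        tr = fg.build_stance_trace(_event(0, 10, (120.0, 45.0)), poses, CFG)
        assert tr.flagged

    def test_forelegs_touch_down_more_anterior(self, trot_track, trot_cfg):
        traces = [fg.build_stance_trace(e, trot_track.poses, trot_cfg)
                  for e in trot_track.events]
        fore = [t.aep.longitudinal for t in traces
                if t.leg in (fg.LegId.LF, fg.LegId.RF)]
        hind = [t.aep.longitudinal for t in traces
                if t.leg in (fg.LegId.LH, fg.LegId.RH)]
        assert min(fore) > max(hind)


class TestStanceLinearity:
    def test_straight_uniform_trace_is_zero(self):
        pts = np.column_stack([np.linspace(0.3, -0.3, 30),
                               np.full(30, 0.1)])
        tr = coord.StanceTrace(leg=fg.LegId.LF, frames=np.arange(30),
                               points=pts)
        assert fg.stance_linearity_index(tr, smooth_win=15) == pytest.approx(
            0.0, abs=1e-12)

    def test_short_trace_undefined(self):
        tr = coord.StanceTrace(leg=fg.LegId.LF, frames=np.arange(5),
                               points=np.zeros((5, 2)))
        assert fg.stance_linearity_index(tr, smooth_win=15) is None

    def test_single_displaced_point_matches_enumeration(self):
        """7-point trace, one lateral kink, window 3: brute-force oracle."""
        n, d, win = 7, 0.05, 3
        pts = np.column_stack([np.linspace(0, 0.6, n), np.zeros(n)])
        pts[3, 1] += d
        # direct enumeration of the shrunk centered moving average
        expected_dev = []
        for i in range(n):
            h = min(win // 2, i, n - 1 - i)
            sm = pts[i - h:i + h + 1].mean(axis=0)
            expected_dev.append(np.hypot(*(pts[i] - sm)))
        expected = float(np.mean(expected_dev))
        assert expected > 0
        tr = coord.StanceTrace(leg=fg.LegId.LF, frames=np.arange(n),
                               points=pts)
        assert fg.stance_linearity_index(tr, smooth_win=win) == \
            pytest.approx(expected, abs=1e-15)

    def test_monotone_in_lateral_noise(self):
        rng = np.random.default_rng(21)
        base = np.column_stack([np.linspace(0.4, -0.4, 60), np.zeros(60)])
        noise = rng.normal(0, 1, size=60)
        vals = []
        for sigma in (0.001, 0.005, 0.02):
            pts = base.copy()
            pts[:, 1] += sigma * noise
            tr = coord.StanceTrace(leg=fg.LegId.LF, frames=np.arange(60),
                                   points=pts)
            vals.append(fg.stance_linearity_index(tr, smooth_win=15))
        assert vals[0] < vals[1] < vals[2]

    def test_nonnegative_on_real_traces(self, trot_track, trot_cfg):
        traces = [fg.build_stance_trace(e, trot_track.poses, trot_cfg)
                  for e in trot_track.events]
        for t in traces:
            v = fg.stance_linearity_index(t, smooth_win=5)
            assert v is None or v >= 0


def _trace(leg, aep, pep):
    pts = np.vstack([aep, pep]).astype(float)
    return coord.StanceTrace(leg=leg, frames=np.arange(2), points=pts)


class TestFootprintClustering:
    def test_identical_endpoints_give_zero(self):
        traces = [_trace(fg.LegId.LF, (0.2, 0.1), (-0.1, 0.1))
                  for _ in range(4)]
        assert fg.footprint_clustering(traces, "AEP") == pytest.approx(0.0)
        assert fg.footprint_clustering(traces, "PEP") == pytest.approx(0.0)

    def test_two_step_variance(self):
        traces = [_trace(fg.LegId.LF, (0.1, 0.0), (0.0, 0.0)),
                  _trace(fg.LegId.LF, (0.3, 0.0), (0.0, 0.0))]
        # population variance of {0.1, 0.3} is 0.01 -> standard distance 0.1
        assert fg.footprint_clustering(traces, "AEP") == pytest.approx(0.1)

    def test_single_step_legs_undefined(self):
        traces = [_trace(fg.LegId.LF, (0.1, 0.0), (0.0, 0.0)),
                  _trace(fg.LegId.RH, (0.2, 0.0), (0.0, 0.0))]
        assert fg.footprint_clustering(traces, "AEP") is None

    def test_invariant_under_arena_rotation(self, trot_track, trot_cfg):
        """Body-frame normalization removes the camera orientation."""
        phi, ox, oy = 0.7, 40.0, -25.0
        c, s = np.cos(phi), np.sin(phi)

        def rot(p):
            return (ox + p[0] * c - p[1] * s, oy + p[0] * s + p[1] * c)

        poses = {f: make_pose(frame=f, center=rot(p.body_center),
                              orientation=p.body_orientation + phi,
                              body_length=p.body_length)
                 for f, p in trot_track.poses.items()}
        events = [fg.StanceEvent(
            onset_frame=e.onset_frame, offset_frame=e.offset_frame,
            centroids=np.array([rot(xy) for xy in e.centroids]),
            areas=e.areas, brightness=e.brightness, leg=e.leg)
            for e in trot_track.events]
        t0 = [fg.build_stance_trace(e, trot_track.poses, trot_cfg)
              for e in trot_track.events]
        t1 = [fg.build_stance_trace(e, poses, trot_cfg) for e in events]
        for ep in ("AEP", "PEP"):
            assert fg.footprint_clustering(t1, ep) == pytest.approx(
                fg.footprint_clustering(t0, ep), abs=1e-9)


class TestFrameCombination:
    def test_exhaustive_enumeration_category_counts(self):
        """All 16 stance/swing combinations map to the seven categories."""
        counts = {c: 0 for c in coord.CATEGORIES}
        for bits in range(16):
            flags = {leg: bool(bits >> i & 1)
                     for i, leg in enumerate(fg.LEGS)}
            counts[fg.frame_combination(flags)] += 1
        assert counts == {"no_swing": 1, "single": 4, "diagonal": 2,
                          "lateral": 2, "front_or_hind": 2, "three_leg": 4,
                          "all_legs": 1}

    def test_diagonal_pair(self):
        flags = {fg.LegId.LF: False, fg.LegId.RH: False,
                 fg.LegId.RF: True, fg.LegId.LH: True}
        assert fg.frame_combination(flags) == "diagonal"

    def test_all_stance_is_no_swing(self):
        assert fg.frame_combination({leg: True for leg in fg.LEGS}) == \
            "no_swing"

    def test_indexes_sum_to_one(self, trot_analysis):
        total = sum(trot_analysis.indexes[c] for c in coord.CATEGORIES)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_all_diagonal_frames(self):
        idx = fg.combination_indexes(["diagonal"] * 10)
        assert idx["diagonal"] == 1.0
        assert sum(idx[c] for c in coord.CATEGORIES) == 1.0

    def test_no_classified_frames_raise(self):
        with pytest.raises(ValueError):
            fg.combination_indexes([])


def _cycles(onsets, leg=fg.LegId.LF):
    out = []
    for a, b in zip(onsets, onsets[1:]):
        out.append(fg.StepCycle(leg=leg, stance_onset=a, stance_offset=a + 5,
                                next_stance_onset=b,
                                stance_time=(6) / 250.0,
                                swing_time=(b - a - 6) / 250.0,
                                period=(b - a) / 250.0, step_length=30.0))
    return out


class TestContralateralPhase:
    def test_mid_cycle_partner_is_antiphase(self):
        ref = _cycles([0, 100, 200, 300])
        est = fg.contralateral_phase(ref, [50, 150, 250], "fore")
        assert est.mean_phase == pytest.approx(0.5)
        assert est.dispersion == pytest.approx(0.0, abs=1e-12)

    def test_synchronous_partner_is_zero(self):
        ref = _cycles([0, 100, 200, 300])
        est = fg.contralateral_phase(ref, [0, 100, 200], "fore")
        assert est.mean_phase == pytest.approx(0.0)

    def test_wraparound_uses_circular_mean(self):
        """Phases {0.95, 0.05} average to 0.0, not 0.5."""
        ref = _cycles([0, 100, 200, 300])
        est = fg.contralateral_phase(ref, [95, 105], "fore")
        assert min(est.mean_phase, 1 - est.mean_phase) == pytest.approx(
            0.0, abs=1e-9)

    def test_circular_mean_matches_scipy(self):
        rng = np.random.default_rng(13)
        phases = (rng.normal(0.0, 0.05, size=40)) % 1.0
        mean, sd = fg.circular_mean_phase(phases)
        ang = 2 * np.pi * np.asarray(phases)
        want_mean = sps.circmean(ang) / (2 * np.pi) % 1.0
        want_sd = sps.circstd(ang) / (2 * np.pi)
        assert mean == pytest.approx(want_mean, abs=1e-12)
        assert sd == pytest.approx(want_sd, abs=1e-12)

    def test_too_few_paired_cycles_undefined(self):
        ref = _cycles([0, 100])
        assert fg.contralateral_phase(ref, [], "fore") is None


class TestTailMetrics:
    def _pose_with_tail(self, f, mid_y, base=(100.0, 50.0)):
        pts = [(base[0] - 15, 50.0), (base[0] - 30, mid_y),
               (base[0] - 45, 50.0)]
        return make_pose(frame=f, center=(130.0, 50.0), tail_base=base,
                         tail_points=pts, tail_orientations=[0.0, 0.0, 0.0])

    def test_collinear_tail_zero_angles(self):
        poses = {f: self._pose_with_tail(f, 50.0) for f in range(5)}
        df = fg.tail_metrics(poses, CFG)
        for col in ("proximal_vs_body", "middle_vs_body", "distal_vs_body",
                    "proximal_vs_middle", "distal_vs_middle"):
            np.testing.assert_allclose(df[col], 0.0, atol=1e-12)

    def test_rigid_translation_zero_perpendicular_velocity(self):
        poses = {}
        for f in range(10):
            p = self._pose_with_tail(f, 50.0, base=(100.0 + 2 * f, 50.0))
            p.tail_points = [(x + 2 * f, y) for x, y in
                             self._pose_with_tail(0, 50.0).tail_points]
            poses[f] = p
        df = fg.tail_metrics(poses, CFG)
        np.testing.assert_allclose(df["tail_perp_velocity_cm_s"][1:], 0.0,
                                   atol=1e-9)

    def test_sinusoidal_sway_peak_velocity(self):
        """Mid-point sway A sin(2 pi f t): peak lateral speed 2 pi f A."""
        A_cm, f_hz = 1.0, 2.0
        cfg = fg.TrialConfig()
        poses = {}
        for f in range(500):
            t = f / cfg.frame_rate_hz
            y = 50.0 + A_cm * cfg.px_per_cm * np.sin(2 * np.pi * f_hz * t)
            poses[f] = self._pose_with_tail(f, y)
        df = fg.tail_metrics(poses, cfg)
        peak = np.nanmax(np.abs(df["tail_perp_velocity_cm_s"]))
        assert peak == pytest.approx(2 * np.pi * f_hz * A_cm, rel=0.05)

    def test_missing_tail_yields_nan(self):
        poses = {0: make_pose(frame=0)}
        df = fg.tail_metrics(poses, CFG)
        assert np.isnan(df["middle_vs_body"].iloc[0])


class TestPressureSeries:
    def test_uniform_blob_arithmetic(self):
        ev = _event(0, 1, (10.0, 10.0))
        df = fg.pressure_series(ev, CFG)
        assert df["area_cm2"].iloc[0] == pytest.approx(0.25)
        assert df["intensity"].iloc[0] == pytest.approx(2500.0)
        assert df["pressure"].iloc[0] == pytest.approx(100.0)

    def test_intensity_linear_in_pixel_values(self):
        ev = _event(0, 3, (10.0, 10.0))
        ev2 = _event(0, 3, (10.0, 10.0))
        ev2.brightness = ev.brightness * 2
        a = fg.pressure_series(ev, CFG)
        b = fg.pressure_series(ev2, CFG)
        np.testing.assert_allclose(b["intensity"], 2 * a["intensity"])
        np.testing.assert_allclose(b["pressure"], 2 * a["pressure"])
        np.testing.assert_allclose(b["area_cm2"], a["area_cm2"])

    def test_gap_frames_have_undefined_pressure(self):
        ev = _event(0, 3, (10.0, 10.0))
        ev.areas = np.array([25, 0, 25])
        df = fg.pressure_series(ev, CFG)
        assert np.isnan(df["pressure"].iloc[1])

    def test_rostral_pressure_drift_during_stance(self, trot_track):
        """Brightness centroid shifts toward the toes late in stance."""
        drifts = []
        for e in trot_track.events:
            n = e.n_frames
            third = e.centroids[2 * n // 3:, 0]
            if len(third) >= 3:
                drifts.append(third[-1] - third[0])
        assert drifts and np.mean(drifts) > 0
        assert np.mean([d > 0 for d in drifts]) > 0.9
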