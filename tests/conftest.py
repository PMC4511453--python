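"""Shared fixtures: one default synthetic trot trial, tracked once per session."""

from __future__ import annotations

import numpy as np
import pytest

import ftirgait as fg


@pytest.fixture(scope="session")
def trot_spec() -> fg.SyntheticGaitSpec:
    return fg.SyntheticGaitSpec(seed=7)


@pytest.fixture(scope="session")
def trot_truth(trot_spec) -> fg.GroundTruth:
    return fg.generate_ground_truth(trot_spec)


@pytest.fixture(scope="session")
def trot_frames(trot_truth):
    return fg.render_frames(trot_truth)


@pytest.fixture(scope="session")
def trot_cfg(trot_truth) -> fg.TrialConfig:
    return trot_truth.trial_config()


@pytest.fixture(scope="session")
def trot_track(trot_frames, trot_cfg) -> fg.TrackResult:
    return fg.track_frames(trot_frames, trot_cfg)


@pytest.fixture(scope="session")
def trot_analysis(trot_track) -> fg.TrialAnalysis:
    return fg.analyze_trial(trot_track)


@pytest.fixture(scope="session")
def trot_fixture_dir(tmp_path_factory, trot_truth, trot_frames):
    """The trot trial written to disk as a PNG + config + truth-CSV fixture."""
    d = tmp_path_factory.mktemp("trot_fixture")
    fg.write_fixture(trot_truth, trot_frames, d, overwrite=True)
    return d


def make_pose(frame=0, center=(0.0, 0.0), orientation=0.0,
              body_length=7.0, **kw) -> fg.BodyPose:
    """A minimal hand-built body pose for unit tests."""
    defaults = dict(
        frame=frame,
        nose=(center[0] + 35 * np.cos(orientation),
              center[1] + 35 * np.sin(orientation)),
        head_center=center, head_direction=(np.cos(orientation),
                                            np.sin(orientation)),
        body_center=center, body_orientation=orientation,
        back_point=center, back_direction=(np.cos(orientation),
                                           np.sin(orientation)),
        tail_base=(center[0] - 35 * np.cos(orientation),
                   center[1] - 35 * np.sin(orientation)),
        body_length=body_length)
    defaults.update(kw)
    return fg.BodyPose(**defaults)
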