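"""Shared fixtures: small rendered recordings with ground truth."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from flymag import (
    ClimbKinematics,
    FrameStack,
    TrackTable,
    VideoSpec,
    render_video,
    simulate_climb_trajectories,
)


@pytest.fixture(scope="session")
def small_video():
    """A 200-frame, one-tube, 10-fly recording with known trajectories.

    Slow kinematics keep all flies inside the tube for the whole clip so
    every frame holds exactly ten separated silhouettes.
    """
    kin = ClimbKinematics(n_flies=10, speed_mean=0.3, speed_sd=0.1,
                          pause_prob=0.25, n_trials=1, trial_duration_s=20,
                          fps=10, seed=5)
    spec = VideoSpec(width=200, height=300, n_tubes=1,
                     tube_rois=[(60, 10, 150, 290)], calibration=20 / 270,
                     noise_sd=3.0)
    truth = simulate_climb_trajectories(kin)
    stack = render_video(truth, spec, seed=7)
    return {"kin": kin, "spec": spec, "truth": truth,
            "stack": FrameStack(stack, fps=kin.fps)}


def make_track_table(rows, fps=10.0, group_size=10, tube_length_cm=20.0):
    """Build a TrackTable from (frame, tube, trial, height_cm[, valid]) tuples."""
    recs = []
    for r in rows:
        frame, tube, trial, height = r[:4]
        valid = r[4] if len(r) > 4 else True
        recs.append((frame, frame / fps, tube, trial, 10.0, 10.0, 39.0,
                     10.0, 5.0, height, valid, "" if valid else "test"))
    df = pd.DataFrame(recs, columns=TrackTable.COLUMNS)
    return TrackTable(df, fps=fps, group_size=group_size,
                      tube_length_cm=tube_length_cm)
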