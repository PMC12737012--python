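"""Shared fixtures and independent oracle helpers."""

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from spermtrack.core_io import BBox, TrajectoryRecord, TrajectorySet


def make_tset(rows, frame_rate=50.0):
    """Build a TrajectorySet from (frame, id, left, top, w, h) tuples."""
    return TrajectorySet(
        [TrajectoryRecord(f, i, BBox(l, t, w, h)) for f, i, l, t, w, h in rows],
        frame_rate=frame_rate,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def split_id_scene():
    """One object over 4 frames with perfect boxes; the prediction uses
    id A on frames 1-2 and id B on frames 3-4."""
    gt = make_tset([(f, 1, 10.0 * f, 20.0, 10, 10) for f in range(1, 5)])
    pred = make_tset(
        [(1, 7, 10.0, 20.0, 10, 10), (2, 7, 20.0, 20.0, 10, 10),
         (3, 9, 30.0, 20.0, 10, 10), (4, 9, 40.0, 20.0, 10, 10)]
    )
    return gt, pred
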