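import numpy as np
import pytest

from pedobar.core import PressureFrameSeries, PressureRecording, SensorGrid
from pedobar.synthetic import FootModel, generate_footprint, generate_multistep


@pytest.fixture(scope="session")
def barefoot_session():
    """Default barefoot platform step, fixed seed; treat as read-only."""
    return generate_footprint(FootModel(), seed=1)


@pytest.fixture
def barefoot(barefoot_session):
    rec, gt = barefoot_session
    return rec.copy(), gt


@pytest.fixture(scope="session")
def inshoe_session():
    """Default 3-step in-shoe trial, fixed seed; treat as read-only."""
    return generate_multistep(FootModel(), n_steps=3, seed=3)


@pytest.fixture
def inshoe(inshoe_session):
    rec, gt = inshoe_session
    return rec.copy(), gt


def make_recording(values, pitch=5.0, sampling_rate=100.0, active=None):
    """Small hand-built recording from a (T, R, C) pressure array."""
    values = np.asarray(values, dtype=float)
    _, n_rows, n_cols = values.shape
    grid = SensorGrid.uniform(n_rows, n_cols, pitch, pitch, active=active)
    return PressureRecording(
        frames=PressureFrameSeries(values, sampling_rate), grid=grid
    )


@pytest.fixture
def tiny_rec():
    """3-frame 4x3 recording with simple numbers."""
    vals = np.zeros((3, 4, 3))
    vals[0, 1, 1] = 50.0
    vals[1, 1, 1] = 80.0
    vals[1, 2, 1] = 20.0
    vals[2, 2, 2] = 40.0
    return make_recording(vals)
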