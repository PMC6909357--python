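import numpy as np
import pytest

from chemotrax import (
    CalibrationMetadata,
    ImageStack,
    SimulationConfig,
    Spot,
    Track,
)


@pytest.fixture
def cal():
    """Dendritic-cell-like calibration: 2 um pixels, 2 min frames."""
    return CalibrationMetadata(pixel_size=2.0, frame_interval=2.0)


@pytest.fixture
def big_field_cal():
    """Coarse calibration giving a very large physical field, for motion
    statistics where boundary reflections must be negligible."""
    return CalibrationMetadata(pixel_size=4.0, frame_interval=2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_stack(cal, rng):
    return ImageStack(frames=rng.uniform(0, 100, size=(10, 32, 32)), calibration=cal)


def straight_track(track_id=0, n=6, step=(10.0, 0.0), start=(50.0, 50.0), frame0=0):
    """A ballistic track with a constant step vector per frame."""
    x0, y0 = start
    dx, dy = step
    return Track(
        track_id=track_id,
        spots=[
            Spot(frame=frame0 + i, x=x0 + i * dx, y=y0 + i * dy, quality=1.0)
            for i in range(n)
        ],
    )


def random_track(rng, track_id=0, n=20, scale=5.0, start=(200.0, 200.0)):
    steps = rng.normal(0, scale, size=(n - 1, 2))
    pos = np.vstack([np.array(start), np.array(start) + np.cumsum(steps, axis=0)])
    return Track(
        track_id=track_id,
        spots=[
            Spot(frame=i, x=float(p[0]), y=float(p[1]), quality=1.0)
            for i, p in enumerate(pos)
        ],
    )


@pytest.fixture
def default_sim_config():
    return SimulationConfig(seed=1)
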