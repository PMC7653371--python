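import numpy as np
import pytest

import suturemetrics as sm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def semicircle():
    """Dense semicircle of radius 1, resampled to 500 stations."""
    t = np.linspace(0.0, np.pi, 2000)
    curve = sm.LandmarkCurve("semi", np.column_stack([np.cos(t), np.sin(t)]))
    return sm.resample_equidistant(curve, 500)


@pytest.fixture
def sine_wave():
    """Regular 8-cycle interdigitated suture, amplitude 0.05."""
    return sm.generate_suture(
        sm.SutureParams(amplitude=0.05, frequency=8, seed=1), specimen_id="wave"
    )


@pytest.fixture
def straight_curve():
    return sm.generate_suture(sm.SutureParams(amplitude=0.0), specimen_id="flat")


def rigid_transform(coords, angle, translation, scale=1.0):
    """Apply a similarity transform (rotation + translation + scale)."""
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    return scale * coords @ rot.T + np.asarray(translation)
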