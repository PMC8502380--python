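import numpy as np
import pytest

from urchinwalk import Trajectory


def make_traj(points, frame_interval=30.0, traj_id="t", treatment=None):
    return Trajectory(
        id=traj_id,
        positions=np.asarray(points, dtype=float),
        frame_interval=frame_interval,
        treatment=treatment,
    )


@pytest.fixture
def straight_traj():
    """10 equally spaced collinear points along +x."""
    return make_traj([(i, 0.0) for i in range(10)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
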