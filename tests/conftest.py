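import numpy as np
import pytest

from jointcal import ARAMIS, ROBOT, PointSet, SyntheticScenario, make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def octahedron():
    """Six symmetric points on the unit sphere."""
    return np.array(
        [
            [1, 0, 0], [-1, 0, 0],
            [0, 1, 0], [0, -1, 0],
            [0, 0, 1], [0, 0, -1],
        ],
        dtype=float,
    )


def small_arcs(n_total=30):
    """A compact ROM arc set keeping C(n,4) small for fast robust fits."""
    from jointcal import ArcSpec

    a = n_total // 3
    return (
        ArcSpec("flexion_extension", 0.0, 90.0, n_total - 2 * a),
        ArcSpec("abduction_adduction", -22.5, 22.5, a),
        ArcSpec("circumduction", 0.0, 360.0, a, cone_deg=15.0),
    )


@pytest.fixture
def noiseless_dataset():
    s = SyntheticScenario(seed=7, noise_sd=0.0, rom_arcs=small_arcs(30))
    return make_dataset(s)


@pytest.fixture
def noisy_dataset():
    s = SyntheticScenario(seed=8, noise_sd=0.1, rom_arcs=small_arcs(30))
    return make_dataset(s)


def zeroed(points, frame=ARAMIS):
    """Build an already-zeroed PointSet from raw coordinates."""
    from jointcal import zero_shift

    return zero_shift(PointSet(frame=frame, points=np.asarray(points, float)))


@pytest.fixture
def robot_frame():
    return ROBOT
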