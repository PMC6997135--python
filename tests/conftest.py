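import numpy as np
import pytest
from hypothesis import settings

from compmd.synth import FixtureSpec, make_helix, make_two_state_ensemble
from compmd.traj_io import Trajectory

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def helix10():
    return make_helix(10)


@pytest.fixture(scope="session")
def two_state_small():
    """300-frame two-basin ensemble, small enough for O(n²) analyses."""
    return make_two_state_ensemble(FixtureSpec(seed=11, n_frames=300))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_cloud_trajectory(rng, n_frames=4, n_atoms=12):
    """Random point-cloud trajectory (no chemistry) for geometry tests."""
    base = make_helix(max(2, n_atoms // 4 + 1))
    topology = base.topology[:n_atoms]
    xyz = rng.normal(scale=4.0, size=(n_frames, n_atoms, 3))
    return Trajectory(topology=topology, xyz=xyz)
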