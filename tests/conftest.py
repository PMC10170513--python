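import numpy as np
import pytest

import metadrt as m


@pytest.fixture(scope="session")
def pseudo_complex():
    """One reproducible cage/ligand system with its 5-CV set."""
    return m.generate_pseudo_complex(seed=3)


@pytest.fixture(scope="session")
def fixture_system():
    """The standard 8 k_BT double-well system used by the recovery tests."""
    return m.build_system(m.double_well_fixture(8.0))


@pytest.fixture(scope="session")
def flooding_trajectory(fixture_system):
    """One well-tempered run on the standard fixture (shared, read-only)."""
    return m.run_metad(
        fixture_system,
        m.FLOODING_PARAMS,
        m.DepositionSchedule(stride=1.0, max_time=2000.0),
        seed=11,
    )


def random_rigid_motion(rng):
    """A random rotation matrix and translation vector."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    return rot.as_matrix(), rng.normal(scale=10.0, size=3)
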