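import numpy as np
import pytest

from altconf.fixtures import FixtureSpec, make_end_states, make_ensemble


@pytest.fixture(scope="session")
def default_spec():
    return FixtureSpec(seed=13)


@pytest.fixture(scope="session")
def end_states(default_spec):
    return make_end_states(default_spec)


@pytest.fixture(scope="session")
def ensemble(default_spec):
    return make_ensemble(default_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_rigid(rng):
    """A random proper rotation matrix and translation vector."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(rng=rng).as_matrix()
    trans = rng.normal(0, 10.0, 3)
    return rot, trans
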