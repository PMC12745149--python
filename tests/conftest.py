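import numpy as np
import pytest

from lvatlas.template import make_template


@pytest.fixture(scope="session")
def small_template():
    """Reduced-resolution template (301 points/surface) for fast tests."""
    return make_template(p_per_surface=301)


@pytest.fixture(scope="session")
def default_template():
    """Full-resolution template (781 points/surface, 1562 total)."""
    return make_template()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rigid(rng):
    from scipy.spatial.transform import Rotation
    from lvatlas.align import RigidTransform
    r = Rotation.random(random_state=np.random.RandomState(
        rng.integers(2 ** 31))).as_matrix()
    t = rng.uniform(-20, 20, 3)
    return RigidTransform(r, t)
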