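import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from asakin import SimulationConfig, simulate_knee


def random_pose_arrays(rng, translation_scale=1.0):
    """A uniformly random proper rotation and a random translation."""
    q = rng.normal(size=4)
    R = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
    p = rng.uniform(-translation_scale, translation_scale, size=3)
    return R, p


@pytest.fixture(scope="session")
def default_trial():
    """Default gait-like synthetic trial: 101 samples, double-hump flexion,
    small out-of-plane motion, femur moving in the lab."""
    return simulate_knee(SimulationConfig())


@pytest.fixture(scope="session")
def pure_hinge_trial():
    """Noiseless planar hinge with a raised-cosine flexion profile."""
    cfg = SimulationConfig(
        flexion_profile="raised_cosine", out_of_plane_amplitude=0.0
    )
    return simulate_knee(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230500)
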