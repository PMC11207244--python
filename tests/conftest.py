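import numpy as np
import pytest

from poseangle import HumanoidSpec, PoseVector, forward_kinematics


@pytest.fixture(scope="session")
def spec():
    return HumanoidSpec()


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def random_pose(spec):
    """Factory for random in-bounds poses, kept away from the bound edges."""

    def make(rng, margin=0.15):
        return PoseVector(tuple(
            lo + (hi - lo) * rng.uniform(margin, 1 - margin)
            for lo, hi in spec.bounds_vector()
        ))

    return make


@pytest.fixture
def reference_joints(spec):
    return forward_kinematics(PoseVector.reference(), spec)
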