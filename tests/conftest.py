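import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_poses(rng):
    """A batch of random poses for metric property tests."""
    from hydrosite.geometry import WaterPose
    from hydrosite.synthetic import uniform_quaternion
    n = 64
    pos = rng.normal(0.0, 2.0, (n, 3))
    quat = uniform_quaternion(rng, n)
    return [WaterPose(p, q, i) for i, (p, q) in enumerate(zip(pos, quat))]
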