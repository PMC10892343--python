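import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_unit_quaternions(rng):
    q = rng.normal(size=(1000, 4))
    return q / np.linalg.norm(q, axis=1, keepdims=True)


def make_uniform_stream(kind, values, rate=100.0, t0=0.0):
    """Helper: wrap a value array in a SensorStream on a uniform grid."""
    from frtkit.preprocess import SensorStream

    n = len(values)
    t = t0 + np.arange(n) / rate
    return SensorStream(kind=kind, t_ns=np.round(t * 1e9).astype(np.int64), values=values)
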