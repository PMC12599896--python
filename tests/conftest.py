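import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

FS = 208.03


@pytest.fixture
def fs():
    return FS


@pytest.fixture
def tone_5hz():
    """60 s unit 5 Hz cosine with its exact phase track."""
    from tremortrack import gen_pure_sine

    return gen_pure_sine(5.0, FS, duration_s=60.0)


@pytest.fixture
def noisy_tone():
    """20 s 5 Hz cosine with mild white noise (for equivalence checks)."""
    from tremortrack import gen_pure_sine

    x, _ = gen_pure_sine(5.0, FS, duration_s=20.0)
    rng = np.random.default_rng(42)
    return x + 0.1 * rng.standard_normal(len(x))
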