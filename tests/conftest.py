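import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def probe():
    from cardiomech.datatypes import ProbeSpec

    return ProbeSpec(radius=2.385e-6, poisson=0.5)


@pytest.fixture
def bimodal_image(rng):
    """Well-separated two-mode image with its truth mask."""
    fg = rng.random((200, 200)) < 0.3
    img = np.where(fg, rng.normal(180.0, 5.0, (200, 200)), rng.normal(20.0, 5.0, (200, 200)))
    return img, fg
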