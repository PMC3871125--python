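import numpy as np
import pytest

from veinmatch.config import RunConfig
from veinmatch.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_config():
    return RunConfig()


@pytest.fixture(scope="session")
def sample_phantom():
    """One deterministic default phantom shared by read-only tests."""
    return generate_phantom(PhantomSpec(seed=7))


def straight_vessel_lines(width_px: float = 5.0, row: float = 41.0,
                          img_width: int = 221):
    """Analytic centerline of one straight horizontal vessel."""
    xs = np.linspace(0.0, img_width - 1.0, 4 * img_width)
    ys = np.full_like(xs, row)
    return [(xs, ys, width_px)]
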