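import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lingscape.synthetic_world import SynthConfig, generate_world

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic world shared across tests (seed fixed)."""
    config = SynthConfig(
        seed=42,
        extent=(-20.0, 20.0, -30.0, 30.0),
        n_languages=20,
        raster_cell_deg=0.5,
    )
    return generate_world(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
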