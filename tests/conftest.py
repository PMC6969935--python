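import numpy as np
import pytest

from gazeval import geometry, synthetic
from gazeval.io_formats import SessionMeta


@pytest.fixture(scope="session")
def desk_screen():
    return synthetic.PLATFORM_GEOMETRY["desk"]


@pytest.fixture(scope="session")
def desk_grid(desk_screen):
    return synthetic.make_stimulus_grid(desk_screen)


@pytest.fixture(scope="session")
def desk_meta():
    return SessionMeta(1, "60", "desk", user_distance_mm=600.0, sampling_rate_hz=60.0)


@pytest.fixture(scope="session")
def noisy_raw(desk_meta, desk_screen, desk_grid):
    """One simulated 2700-sample session with moderate bias/noise/outliers."""
    model = synthetic.ConditionModel("60", bias_deg=2.0, sigma_deg=0.3, outlier_rate=0.01)
    return synthetic.simulate_session(desk_meta, desk_screen, desk_grid, model, seed=42)


@pytest.fixture(scope="session")
def noisy_session(desk_meta, desk_screen, noisy_raw):
    return geometry.process_session(desk_meta, desk_screen, noisy_raw)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
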