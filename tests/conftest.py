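import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from refnorm import SimulationConfig  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def quiet_config():
    """Noise-free small configuration: every output is deterministic."""
    return SimulationConfig(
        n_genes=20, frac_up=0.1, frac_down=0.1,
        biological_noise_sd=0.0, sample_scale_sd=0.0, cq_noise_sd=0.0,
        seed=7,
    )


@pytest.fixture
def tidy_series():
    """A complete 3-day x 2-replicate measurement grid for one gene."""
    return pd.DataFrame({
        "day": [0, 0, 3, 3, 10, 10],
        "replicate": ["a", "b"] * 3,
        "value": [50.0, 100.0, 60.0, 120.0, 100.0, 300.0],
    })
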