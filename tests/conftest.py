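import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stormquant.simulate import SimConfig, simulate_cell

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
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def default_cell():
    """One simulated cell at default SNR, shared across read-only tests."""
    cfg = SimConfig(seed=11, n_cytosolic_clusters=8, min_domain_separation_nm=160.0)
    return cfg, simulate_cell(cfg)
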