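import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from microfunc import simulate as sim

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_gcn():
    """40 functions x 60 microbes, integer copy numbers."""
    return sim.make_gcn(n_functions=40, n_microbes=60, density=0.4, copy_max=20, seed=11)


@pytest.fixture
def small_table():
    """60 microbes x 25 samples, matching small_gcn's microbe ids."""
    return sim.make_abundance_table(n_microbes=60, n_samples=25, mean_depth=5000, seed=11)
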