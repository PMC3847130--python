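import pytest
from hypothesis import HealthCheck, settings

from swarmselect import SwarmConfig, make_expression

settings.register_profile(
    "repro",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture
def tiny_synthetic():
    """12 samples x 8 genes, 2 classes, 2 strongly planted genes."""
    return make_expression(n_samples=12, n_genes=8, n_classes=2,
                           n_informative=2, effect_size=6.0, seed=1)


@pytest.fixture
def tiny_dataset(tiny_synthetic):
    return tiny_synthetic.dataset


@pytest.fixture
def small_config():
    return SwarmConfig(num_particles=5, max_iter=5, seed=3)
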