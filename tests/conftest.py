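import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from misplice import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small mixed-type dataset with genome, gene sets and planted effects."""
    cfg = SimConfig(
        seed=42, n_genes=60, events_per_gene_mean=2.0,
        n_case=6, n_ctrl=5, frac_mis_spliced=0.15,
        n_sets=5, set_size=10, with_genome=True,
        coverage_mean=150.0,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
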