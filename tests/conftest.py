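import numpy as np
import pytest

from dualinit import sim


@pytest.fixture(scope="session")
def small_dataset():
    """A 300-gene simulated reference with CTSS tracks (session-cached)."""
    genome, genes, truth = sim.generate_reference(
        300, seed=11, dual_fraction=0.3)
    tables = sim.simulate_ctss_counts(truth, depth=300_000, seed=12)
    return genome, genes, truth, tables


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
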