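import pytest
from hypothesis import settings

import strigasoil as ss

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_bundle():
    """One small rhizosphere bundle (20 taxa, 4 reps/cell, both timepoints)."""
    config = ss.SimConfig(
        n_taxa=20, n_replicates=4, sub_categories=("rhizosphere",), seed=11
    )
    taxa, traits, truth = ss.simulate_dataset(config)
    return config, taxa, traits, truth


@pytest.fixture()
def fast_mcmc():
    """Short but valid chain (500 retained draws) for unit tests."""
    return ss.McmcSettings(n_iter=1500, burn_in=500, thin=2, seed=5)
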