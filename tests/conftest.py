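import numpy as np
import pytest
from hypothesis import settings

import beadcolony as bc

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_mono_params():
    b = bc.MonocultureParams(r=0.56, gamma=1.2, a1=10.0, a2=1000.0)
    y = bc.MonocultureParams(r=0.70, gamma=1.2, a1=10.0, a2=1200.0)
    return b, y


@pytest.fixture(scope="session")
def study_time_points():
    return np.array([4.0, 6.0, 8.0, 10.0, 12.0, 22.0, 32.0])


@pytest.fixture(scope="session")
def small_table():
    """A modest default-condition co-culture table shared across tests."""
    return bc.generate_experiment(bc.ExperimentConfig(n_beads=150, seed=42))


@pytest.fixture(scope="session")
def huge_table():
    """Large-bead-count table for law-of-large-numbers checks."""
    return bc.generate_experiment(bc.ExperimentConfig(n_beads=100_000, seed=5))
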