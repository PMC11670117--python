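import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import endokit as ek

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_experiment() -> ek.SimulatedExperiment:
    """A modest synthetic study shared by read-only tests."""
    cfg = ek.SimConfig(n_proteins=300, seed=7)
    return ek.simulate_experiment(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240)
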