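import numpy as np
import pytest

from fesfatigue import FesTrialSpec, analyze_fes_trial, simulate_fes_trial


@pytest.fixture(scope="session")
def canonical_sim():
    """Default synthetic FES trial (24 Hz, 200 us, 12 mA), fixed seed."""
    return simulate_fes_trial(FesTrialSpec(seed=7))


@pytest.fixture(scope="session")
def canonical_fes_result(canonical_sim):
    """Full pipeline result (separation -> RMS -> fit -> stages) for it."""
    return analyze_fes_trial(canonical_sim.mixed)


@pytest.fixture()
def rng():
    return np.random.default_rng(20241)
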