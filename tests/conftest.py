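import warnings

import pytest

from acvs.simulate import SimulationConfig, simulate_study

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def behavioral_study():
    """Small choice-only study reused across behavioral tests."""
    cfg = SimulationConfig(n_participants=8, n_practice=1, n_main=2,
                           fixations=False, seed=42)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def fixation_study():
    """Small study with displays and fixation sequences."""
    cfg = SimulationConfig(n_participants=6, n_practice=0, n_main=2,
                           fixations=True, seed=7)
    return simulate_study(cfg)
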