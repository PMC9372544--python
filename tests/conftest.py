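import numpy as np
import pytest

from teamsync import event_model, synthetic


@pytest.fixture(scope="session")
def male_sim():
    """One simulated male-profile experiment (16 matches, Sy boost on)."""
    return synthetic.simulate_experiment(synthetic.male16(seed=11))


@pytest.fixture(scope="session")
def null_sim():
    """One simulated null experiment (14 matches, no condition effects)."""
    return synthetic.simulate_experiment(synthetic.female14(seed=12))


@pytest.fixture(scope="session")
def stroop_sim():
    """Full study-sized Stroop simulation (all groups, no tempo effects)."""
    return synthetic.simulate_stroop(synthetic.StroopSimConfig(seed=13))


@pytest.fixture
def tiny_possessions():
    """Hand-written possessions of a single team-third."""
    return [
        event_model.Possession("M1", "T1", "wR", 0, 3, 5, True),
        event_model.Possession("M1", "T1", "wR", 1, 0, 2, False),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
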