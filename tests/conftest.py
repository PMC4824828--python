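import numpy as np
import pytest

from stresslab.lexicon import build_training_sets
from stresslab.observer import PRESETS, simulate_cohort
from stresslab.schedule import BUDGERIGAR, HUMAN


@pytest.fixture(scope="session")
def word_sets():
    return build_training_sets()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def human_cohort():
    """20 human-like subjects through the full protocol (counterbalanced)."""
    return simulate_cohort(PRESETS["human_like"], HUMAN, 20, seed=0)


@pytest.fixture(scope="session")
def budgie_cohort():
    """20 budgie-like subjects through the full protocol (counterbalanced)."""
    return simulate_cohort(PRESETS["budgie_like"], BUDGERIGAR, 20, seed=0)


@pytest.fixture(scope="session")
def human_cohort_logs(human_cohort):
    return [r.records for r in human_cohort if r.completed]


@pytest.fixture(scope="session")
def budgie_cohort_logs(budgie_cohort):
    return [r.records for r in budgie_cohort if r.completed]
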