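import numpy as np
import pytest

from wordrep.environment import TrialConfig
from wordrep.inference import InferenceSettings, run_trial
from wordrep.model import build_word_repetition_model
from wordrep.plasticity import accumulate_dirichlet


@pytest.fixture(scope="session")
def spurious_model():
    return build_word_repetition_model(spurious=True)


@pytest.fixture(scope="session")
def small_learned_model():
    """One subject after a short acquisition run (fast; for unit tests)."""
    from wordrep.experiments import run_learning_phase

    return run_learning_phase(n_subjects=1, n_trials=300, base_seed=12345).models[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
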