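import numpy as np
import pandas as pd
import pytest

from bbscore import simulate


@pytest.fixture(scope="session")
def word_cohort():
    """Default-scale word-trial cohort with shared rho = 0.35 and its truth."""
    spec = simulate.CohortSpec(seed=11, sentence_trials=0)
    params = simulate.generate_cohort(spec)
    trials = simulate.generate_trials(params, spec)
    return spec, params, trials


@pytest.fixture(scope="session")
def small_cohort():
    """Small cohort (5 participants x 80 word trials) for quick fits."""
    spec = simulate.CohortSpec(
        n_participants=5, word_trials=80, sentence_trials=0, seed=23
    )
    params = simulate.generate_cohort(spec)
    trials = simulate.generate_trials(params, spec)
    return spec, params, trials


@pytest.fixture()
def single_participant_trials():
    """One participant, 20 word trials of n=3 with exactly 20/60 tokens correct."""
    return pd.DataFrame(
        {
            "participant_id": "A",
            "trial_id": [f"t{i:02d}" for i in range(20)],
            "n_tokens": 3,
            "n_correct": np.array([1] * 20),
        }
    )
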