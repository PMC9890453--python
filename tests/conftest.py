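import numpy as np
import pandas as pd
import pytest

from erpmix import GenerativeParams, build_design, simulate_trials


@pytest.fixture(scope="session")
def tiny_design():
    """Two participants, 4 stimuli per category (32-trial blocks)."""
    return build_design(2, seed=7, n_stimuli_per_category=4)


@pytest.fixture(scope="session")
def quiet_params():
    """All randomness off except detection: deterministic amplitudes."""
    return GenerativeParams(
        sd_participant=0.0,
        sd_stimulus=0.0,
        sd_amp=0.0,
        sd_noise=0.0,
    )


@pytest.fixture(scope="session")
def simulated_trials(tiny_design):
    params = GenerativeParams.all_or_none_preset()
    return simulate_trials(tiny_design, params, seed=11)


def make_face_design(n_trials: int, duration: int = 33, half: int = 1) -> pd.DataFrame:
    """A flat run of intact-face trials for law-of-large-numbers checks."""
    return pd.DataFrame(
        {
            "participant_id": 1,
            "block": 1 if half == 1 else 3,
            "half": half,
            "trial_index": np.arange(1, n_trials + 1),
            "stimulus_id": 1 + (np.arange(n_trials) % 8),
            "category": "face",
            "type": "intact",
            "duration": duration,
        }
    )
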