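import numpy as np
import pandas as pd
import pytest

from driftsem import DDMParams, GeneratorConfig, generate_study


@pytest.fixture(scope="session")
def printed_mean_params():
    """Baseline-condition population parameters used throughout."""
    return DDMParams(v=4.098, a=1.2, t0=0.347, st0=0.15, sv=1.0)


@pytest.fixture(scope="session")
def small_study():
    """A 12-participant synthetic study shared by integration-level tests."""
    cfg = GeneratorConfig(n_participants=12, seed=11)
    return cfg, generate_study(cfg, items=True)


def make_trials(rows):
    """Build a trial DataFrame from (participant, condition, index, rt, response)."""
    return pd.DataFrame(
        rows, columns=["participant_id", "condition", "trial_index", "rt",
                       "response"])
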