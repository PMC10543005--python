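import numpy as np
import pandas as pd
import pytest

from twinplacebo import synth


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    return synth.generate_cohort(synth.CohortSpec(20, 24, 10, seed=7))


@pytest.fixture(scope="session")
def trial_table(small_cohort) -> pd.DataFrame:
    table, _ = synth.simulate_trial_table(small_cohort, seed=7)
    return table


@pytest.fixture(scope="session")
def clean_trials(small_cohort) -> pd.DataFrame:
    """Trial table without planted reaction-time violations."""
    table, _ = synth.simulate_trial_table(
        small_cohort, seed=7, rt_violation_fraction=0.0
    )
    return table


@pytest.fixture(scope="session")
def signature():
    return synth.make_synthetic_signature((16, 16, 16), 2, 6, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
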