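import numpy as np
import pandas as pd
import pytest

from gemtree.synthetic_cohort import default_config, make_cohort


@pytest.fixture(scope="session")
def cohort26() -> pd.DataFrame:
    """One default 26-patient synthetic cohort, shared across tests."""
    return make_cohort(default_config(seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240910)


def exp_cohort(n: int, hazard: float, censor_max: float, rng: np.random.Generator):
    """Plain exponential survival with uniform censoring (no covariate effect)."""
    t_event = rng.exponential(1.0 / hazard, n)
    censor = (1.0 - rng.random(n)) * censor_max
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)
    return time, event
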