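import numpy as np
import pandas as pd
import pytest

from pseudosurv import ScenarioConfig, SurvivalSample, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def censored_sample(rng):
    """Moderately censored exponential sample with one binary covariate."""
    n = 120
    z = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(10.0 / (1.0 + z), n)
    c = rng.exponential(25.0, n)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    return SurvivalSample(
        subject_id=np.arange(n),
        time=time,
        event=event,
        covariates=pd.DataFrame({"z": z}),
    )


@pytest.fixture
def scenario1_sample():
    return simulate_dataset(ScenarioConfig(), 1, seed=20240901)


@pytest.fixture
def scenario2_sample():
    return simulate_dataset(ScenarioConfig(), 2, seed=20240902)
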