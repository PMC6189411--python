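import numpy as np
import pytest

from conjmlm import level2, preprocessing
from conjmlm.synthetic import SyntheticConfig, TruthModel, simulate_dataset

#: study-period average conditions: (T + 20, RH, O₃)
AVG_X = (32.34, 58.5, 0.018)


@pytest.fixture(scope="session")
def small_dataset():
    """A quiet 52-week synthetic dataset over all 18 strata."""
    cfg = SyntheticConfig(
        seed=42, n_weeks=52, count_model="rounded-gaussian", rate_noise=0.0
    )
    env, obs = simulate_dataset(cfg)
    env_t = preprocessing.transform_predictors(env)
    data = obs.merge(env_t[["week", "x1", "x2", "x3"]], on="week")
    split = preprocessing.split_weeks(cfg.n_weeks, 42)
    return data, split


@pytest.fixture(scope="session")
def published_table():
    return level2.CoefficientTable.from_published_table2()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
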