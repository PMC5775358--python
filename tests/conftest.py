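import numpy as np
import pytest

from laborcast.labor_supply import AgeBand
from laborcast.stochastic_simulation import (
    PipelineOptions,
    fit_pipeline,
    synthetic_scenario,
)
from laborcast.synthetic_data import SyntheticConfig, default_lfpr_truth

# two broad participation bands instead of ten keep integration fixtures fast
# without changing any mechanism under test
SMALL_BANDS = (AgeBand(15, 39), AgeBand(40, 64))


def small_config(seed: int = 0, **kwargs) -> SyntheticConfig:
    return SyntheticConfig(
        seed=seed, lfpr_truth=default_lfpr_truth(SMALL_BANDS), **kwargs
    )


def small_options(**kwargs) -> PipelineOptions:
    kwargs.setdefault("end_year", 2025)
    kwargs.setdefault("age_bands", SMALL_BANDS)
    return PipelineOptions(**kwargs)


@pytest.fixture(scope="session")
def tiny_scenario():
    return synthetic_scenario(small_config(seed=7))


@pytest.fixture(scope="session")
def tiny_pipeline(tiny_scenario):
    return fit_pipeline(tiny_scenario, small_options())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
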