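import numpy as np
import pandas as pd
import pytest

from parenclitic import (
    AnalysisConfig,
    SyntheticConfig,
    apply_horizon,
    build_reference_set,
    generate_cohort,
)


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """Default synthetic cohort at seed 1, horizon-censored."""
    return apply_horizon(generate_cohort(SyntheticConfig(seed=1)), 365)


@pytest.fixture(scope="session")
def default_refset(default_cohort):
    return build_reference_set(default_cohort, AnalysisConfig())


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """120-patient cohort for fast end-to-end runs."""
    cfg = SyntheticConfig(n_survivors=90, n_nonsurvivors=30, seed=5)
    return apply_horizon(generate_cohort(cfg), 365)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
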