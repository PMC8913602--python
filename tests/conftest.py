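import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from hbpcount import (
    CohortDesign,
    SimulationDesign,
    apply_exclusions,
    generate_synthetic_cohort,
    run_simulation,
    summarize_series,
)


@pytest.fixture(scope="session")
def sim_summaries() -> pd.DataFrame:
    """Default factorial simulation (1200 rows), shared across tests."""
    return run_simulation(SimulationDesign(seed=0))


@pytest.fixture(scope="session")
def synthetic_cohort():
    """Default synthetic validation cohort after exclusions, with its log."""
    cohort = generate_synthetic_cohort(CohortDesign(seed=0))
    return apply_exclusions(cohort)


@pytest.fixture(scope="session")
def cohort_summaries(synthetic_cohort) -> pd.DataFrame:
    kept, _ = synthetic_cohort
    return pd.DataFrame([summarize_series(s).to_dict() for s in kept])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
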