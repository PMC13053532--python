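import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from panotex.phantom import CohortSpec, ResolutionGroup, cohort_to_dataframe, sample_cohort


@pytest.fixture(scope="session")
def default_cohort_df():
    """The 43-tooth default cohort (22 C-shaped / 21 controls), fixed seed."""
    return cohort_to_dataframe(sample_cohort(CohortSpec(seed=0)))


@pytest.fixture(scope="session")
def null_cohort_df():
    """Label-neutral cohort: no heterogeneity shift, no volume effect."""
    spec = CohortSpec(
        n_c_shaped=100,
        n_control=100,
        resolution_split={
            ResolutionGroup.GROUP_496: (50, 50),
            ResolutionGroup.GROUP_593: (50, 50),
        },
        heterogeneity_effect=0.0,
        volume_effect_d=0.0,
        seed=7,
    )
    return cohort_to_dataframe(sample_cohort(spec))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
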