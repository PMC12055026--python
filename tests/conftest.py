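import numpy as np
import pandas as pd
import pytest

from msngrad import msn as msn_mod
from msngrad import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def toy_table(rng):
    """Small regions x 5 standardized feature table."""
    raw = pd.DataFrame(
        rng.standard_normal((12, 5)), columns=list(syn.FEATURES)
    )
    return msn_mod.zscore_features(raw)


@pytest.fixture(scope="session")
def small_cohort():
    """60-subject, 100-region cohort with a planted group effect, 2 sites."""
    rng = np.random.default_rng(7)
    spec = syn.CohortSpec(
        n_regions=100,
        n_per_group=(30, 30),
        n_sites=2,
        effect_map=rng.normal(0, 0.5, 100),
        site_offsets=rng.normal(0, 0.2, (2, 5)),
        seed=7,
    )
    return syn.generate_cohort(spec)


@pytest.fixture(scope="session")
def small_msns(small_cohort):
    return msn_mod.msn_stack(small_cohort.features)
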