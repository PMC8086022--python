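import numpy as np
import pytest

import sleeptopo as st


@pytest.fixture(scope="session")
def cohort50():
    """Default study-sized cohort (50/group, table mode)."""
    spec = st.CohortSpec(n_per_group=50)
    return st.generate_cohort(spec, seed=42)


@pytest.fixture(scope="session")
def table50(cohort50):
    return st.build_band_power_table(cohort50)


@pytest.fixture(scope="session")
def small_cohort():
    spec = st.CohortSpec(n_per_group=10)
    return st.generate_cohort(spec, seed=7)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return st.build_band_power_table(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
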