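import numpy as np
import pytest

import lifespace as ls


@pytest.fixture(scope="session")
def small_cohort():
    """One default-sized synthetic cohort shared by read-only tests."""
    return ls.generate_cohort(ls.CohortConfig(seed=7))


@pytest.fixture(scope="session")
def small_panel(small_cohort):
    feats = ls.extract_cohort(small_cohort.fixes, small_cohort.demographics)
    pain = ls.aggregate_daily_pain(small_cohort.prompts)
    return ls.build_panel(feats, pain, small_cohort.demographics)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
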