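import warnings

import numpy as np
import pytest

from radsubtype.cluster import zscore_features
from radsubtype.features import build_feature_table
from radsubtype.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 24-sample imaging cohort shared by the clustering tests."""
    return generate_cohort(CohortConfig(n_samples=24, seed=123))


@pytest.fixture(scope="session")
def small_feature_table(small_cohort):
    table, errors = build_feature_table(
        zip(small_cohort.sample_ids, small_cohort.series_list,
            small_cohort.mask_list))
    assert not errors
    return table


@pytest.fixture(scope="session")
def small_scaled(small_feature_table):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scaled, scaling = zscore_features(small_feature_table)
    return scaled, scaling


@pytest.fixture
def rng():
    return np.random.default_rng(42)
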