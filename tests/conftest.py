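import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import gmpatterns as g

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def paper_cohort() -> g.SyntheticCohort:
    """Mid-sized default-scenario cohort with follow-up, shared read-only."""
    return g.generate_cohort(g.default_paper_config(n_subjects=400, seed=2))


@pytest.fixture(scope="session")
def paper_features(paper_cohort):
    return g.build_feature_matrix(paper_cohort.baseline_table)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def two_blob_features(rng, n=120, p=20, n_informative=8, shift=1.6):
    """Two clusters displaced to +/-shift on the informative features."""
    labels = np.repeat([1, 2], n // 2)
    X = rng.standard_normal((n, p))
    X[labels == 1, :n_informative] -= shift
    X[labels == 2, :n_informative] += shift
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(p)]), labels
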