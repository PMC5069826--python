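import numpy as np
import pandas as pd
import pytest

from ffpesig.cohort import CohortConfig, generate_cohort
from ffpesig.matrix import ExpressionMatrix


@pytest.fixture(scope="session")
def default_cohort():
    """A full-size cohort at the default study conditions."""
    return generate_cohort(CohortConfig(seed=20160101))


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort for fast structural checks."""
    cfg = CohortConfig(
        n_samples=12,
        n_background_genes=60,
        n_bad_samples=3,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_log2_matrix(rng, n_features=20, n_samples=8, prefix="F"):
    vals = rng.normal(8.0, 1.5, size=(n_features, n_samples))
    df = pd.DataFrame(
        vals,
        index=[f"{prefix}{i:03d}" for i in range(n_features)],
        columns=[f"S{j:03d}" for j in range(n_samples)],
    )
    return ExpressionMatrix(df, "log2")


@pytest.fixture()
def log2_matrix(rng):
    return random_log2_matrix(rng)
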