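import numpy as np
import pytest

from neuromediate import calibrated, generate_cohort


@pytest.fixture(scope="session")
def cog1_cohort_small():
    """DGP-COG1 cohort at a size suitable for unit tests."""
    return generate_cohort(calibrated.dgp_cog1(n=200_000, seed=42))


@pytest.fixture(scope="session")
def rotterdam_cohort_small():
    cfg = calibrated.rotterdam_like(n=1500, seed=7, with_missingness=False)
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
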