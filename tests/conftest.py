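import numpy as np
import pytest

from fdflim.cohort import CohortConfig
from fdflim.pipeline import run_pipeline

N_COHORTS = 25
COHORT_SEEDS = list(range(1, N_COHORTS + 1))


def _run_all(mode: str):
    return [run_pipeline(CohortConfig(mode=mode, seed=s)) for s in COHORT_SEEDS]


@pytest.fixture(scope="session")
def ala_results():
    """Full pipeline on 25 seeded default cohorts, ALA-conditioned PPIX."""
    return _run_all("ala")


@pytest.fixture(scope="session")
def tissue_results():
    """Full pipeline on 25 seeded default cohorts, tissue-conditioned PPIX."""
    return _run_all("tissue")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
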