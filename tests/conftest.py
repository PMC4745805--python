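import numpy as np
import pytest

from exomarker import SyntheticConfig, generate_cohort
from exomarker.differential import DifferentialAnalyzer

# small detection limit: tiny cohorts have few proteins in the narrow
# abundance band required for detectable down-regulated markers
SMALL_CONFIG = SyntheticConfig(
    seed=7, n_proteins=40, n_up=6, n_down=2, triplicated_samples=2,
    detection_limit=1e5,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(SMALL_CONFIG, include_evidence=True)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size cohort at the study's design defaults (15/16, 1600 proteins)."""
    return generate_cohort(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def default_results(default_cohort):
    analyzer = DifferentialAnalyzer().fit(
        default_cohort.psm, default_cohort.top3tic,
        ibaq_pools=default_cohort.ibaq_pools)
    return analyzer.results_
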