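import warnings

import numpy as np
import pytest

from tos.simulate import SimulationParams, simulate_cohort

# cyvcf2/htslib chatter on minimal headers is irrelevant to the checks
warnings.filterwarnings("ignore", message=".*AD/DP.*")


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale default-scenario cohort shared across test modules."""
    params = SimulationParams(
        n_samples=6, n_germline_small=1200, n_somatic_small=250, seed=11
    )
    return simulate_cohort(params)


@pytest.fixture(scope="session")
def small_cohort_dir(small_cohort, tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    small_cohort.write(out)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
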