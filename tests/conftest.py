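import numpy as np
import pytest

from rsnpfs.parcellation import NETWORK_NAMES
from rsnpfs.synthetic import (
    CovarianceSpec,
    make_cohort,
    make_parcellation,
    simulate_timeseries,
)


@pytest.fixture(scope="session")
def small_parcellation():
    """15 networks x 4 voxels on an 12^3 grid: enough for full feature vectors."""
    return make_parcellation(15, 4, (12, 12, 12), seed=11)


@pytest.fixture(scope="session")
def toy_subject(small_parcellation):
    spec = CovarianceSpec(rho_within=0.5, n_timepoints=80)
    return simulate_timeseries(small_parcellation, spec, seed=5, subject_id="toy")


@pytest.fixture(scope="session")
def toy_cohort(small_parcellation):
    """10 subjects with raw time series; small but runs the full pipeline."""
    return make_cohort(
        n_subjects=10,
        parcellation=small_parcellation,
        n_timepoints=80,
        seed=21,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
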