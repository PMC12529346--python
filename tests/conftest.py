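import numpy as np
import pytest

from capdyn.atlas import default_parcel_table
from capdyn.clustering import concat_frames
from capdyn.io import zscore_session
from capdyn.synthetic import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def parcel_table():
    return default_parcel_table()


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort with the default six planted states,
    simulated once per test session."""
    spec = CohortSpec(
        n_trd=8,
        n_hc=6,
        n_hc_longitudinal=3,
        n_rois=120,
        frames_per_run=80,
        seed=7,
    )
    manifest, sessions, truth = simulate_cohort(spec)
    return spec, manifest, sessions, truth


@pytest.fixture(scope="session")
def small_pool(small_cohort):
    _, _, sessions, _ = small_cohort
    return concat_frames([zscore_session(ts) for ts in sessions])


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
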