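import numpy as np
import pytest

from dcetrunc import (
    RefRegionParams,
    VoxelParams,
    population_aif,
    table1_cohort,
)


@pytest.fixture(scope="session")
def fine_grid():
    """1 s grid over 8 minutes."""
    return np.arange(0, 8.0 + 1e-9, 1.0 / 60.0)


@pytest.fixture(scope="session")
def aif_1s(fine_grid):
    return population_aif(fine_grid, onset_min=1.0)


@pytest.fixture(scope="session")
def rr_params():
    return RefRegionParams()


@pytest.fixture
def tumor_params():
    return VoxelParams(ktrans=0.25, ve=0.4)


@pytest.fixture(scope="session")
def acrin_cohort():
    return table1_cohort("ACRIN")


@pytest.fixture(scope="session")
def single_site_cohort():
    return table1_cohort("single-site")
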