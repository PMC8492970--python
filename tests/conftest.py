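import numpy as np
import pytest

from hemifc import phantom as ph


@pytest.fixture(scope="session")
def small_spec() -> ph.PhantomSpec:
    """Desk-scale phantom on the default grid: short series, 2 subjects per
    group, parcels with the default NC > VMCI > MCI planted correlations."""
    return ph.PhantomSpec(n_timepoints=40, groups={"NC": 2, "VMCI": 2, "MCI": 2}, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_spec) -> ph.Cohort:
    return ph.generate_cohort(small_spec)


@pytest.fixture(scope="session")
def compartments(small_spec):
    return ph.tissue_compartments(small_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
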