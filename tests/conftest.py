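import numpy as np
import pytest

import subgrad as sg


@pytest.fixture(scope="session")
def line_geometry():
    """A 4-voxel line whose hierarchy axis is forced to (0, 1/3, 2/3, 1)."""
    return sg.make_geometry((4, 1, 1), 2, seed=0, n_cortical_rois=10)


@pytest.fixture(scope="session")
def small_geometry():
    return sg.make_geometry((5, 4, 2), 7, seed=1, n_cortical_rois=30)


@pytest.fixture(scope="session")
def small_cohort():
    return sg.simulate_twin_cohort(30, 30, 5, 5, seed=7)


@pytest.fixture(scope="session")
def big_pair_cohort():
    """2000 MZ + 2000 DZ pairs: enough for tight parameter recovery."""
    return sg.simulate_twin_cohort(2000, 2000, 0, 0, seed=17)
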