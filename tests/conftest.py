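import numpy as np
import pytest

from congrad import generate_bold, group_gradients, make_scenario, planted_modes


@pytest.fixture(scope="session")
def scenario():
    """Default synthetic cohort: 24^3 grid, ~330-voxel two-ellipsoid ROI,
    2 planted modes, 4 network parcels, 200 timepoints, 20 subjects."""
    return make_scenario()


@pytest.fixture(scope="session")
def truth(scenario):
    return planted_modes(scenario)


@pytest.fixture(scope="session")
def runs(scenario, truth):
    return [generate_bold(scenario, s, truth)
            for s in range(scenario.n_subjects)]


@pytest.fixture(scope="session")
def group_grads(runs):
    return group_gradients(runs, 6)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
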