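import warnings

import numpy as np
import pytest

from rfsp import GridSpec, PointSet, VariogramModel
from rfsp.synthfields import FieldSpec, make_dataset, sample_design, simulate_grf


@pytest.fixture(autouse=True)
def _quiet_degree_warnings():
    """Small unit-test grids sit inside the lon/lat heuristic range."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*lon/lat degrees.*")
        warnings.filterwarnings("ignore", message=".*duplicate coordinates.*")
        yield


@pytest.fixture
def grid20():
    return GridSpec(origin=(0.0, 20.0), cell_size=1.0, nrows=20, ncols=20)


@pytest.fixture
def grid40():
    return GridSpec(origin=(0.0, 40.0), cell_size=1.0, nrows=40, ncols=40)


@pytest.fixture
def vgm_exp():
    return VariogramModel("exponential", nugget=0.1, psill=1.0, range_param=5.0)


@pytest.fixture
def field40(grid40, vgm_exp):
    return simulate_grf(FieldSpec(grid=grid40, vgm=vgm_exp, seed=11))


@pytest.fixture
def ps120(field40, grid40):
    locs = sample_design(grid40, 120, seed=12)
    return make_dataset(field40, locs, seed=13)


@pytest.fixture
def rng():
    return np.random.default_rng(202409)


def random_pointset(rng, n=20, extent=100.0, jitter=True):
    coords = rng.uniform(0, extent, size=(n, 2))
    if jitter:  # avoid accidental duplicates
        coords += rng.normal(0, 1e-6, size=(n, 2))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return PointSet(coords=coords, target=rng.normal(size=n))
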