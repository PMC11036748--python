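import numpy as np
import pytest

from cortisel.landscape import COVER, CROPLAND, LandscapeGrid, make_landscape
from cortisel.recovery import simulate_issa_study
from cortisel.synthetic import SimConfig


@pytest.fixture(scope="session")
def landscape():
    return make_landscape(seed=42)


@pytest.fixture(scope="session")
def single_cover_grid():
    """5x5 cropland grid with one cover cell at the centre, 100-m cells."""
    habitat = np.full((5, 5), CROPLAND, dtype=np.int8)
    habitat[2, 2] = COVER
    return LandscapeGrid(habitat=habitat, cell_size=100.0)


@pytest.fixture(scope="session")
def small_study():
    """A compact simulated bout study shared by the estimation tests."""
    return simulate_issa_study(n_individuals=6, bouts_per_individual=4, seed=202)


@pytest.fixture(scope="session")
def small_fit(small_study):
    from cortisel.recovery import refit_study

    return refit_study(small_study, K=20, seed=7)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small full synthetic bundle (tracks, samples, events)."""
    from cortisel.synthetic import simulate_dataset

    cfg = SimConfig(
        n_individuals=4, years=(2019,), season=((6, 1), (6, 20)),
        calving_window=((6, 3), (6, 10)), samples_per_individual=3, seed=99,
    )
    return simulate_dataset(cfg)
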