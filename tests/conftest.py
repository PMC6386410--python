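import numpy as np
import pytest

from ecogdac import ElectrodeGrid, build_distance_structure


@pytest.fixture
def grid_2x2():
    return ElectrodeGrid.rectangular(2, 2, 1.0)


@pytest.fixture
def grid_7x8():
    """56-channel grid at 0.4 mm pitch (the human micro-ECoG layout)."""
    return ElectrodeGrid.rectangular(7, 8, 0.4)


@pytest.fixture
def model_grid_10x15():
    return ElectrodeGrid.rectangular(10, 15, 1.0)


@pytest.fixture
def ds_7x8(grid_7x8):
    return build_distance_structure(grid_7x8)


@pytest.fixture
def colocated_grid():
    """Two channels at one position plus two more; test-only geometry."""
    pos = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    return ElectrodeGrid(["a", "b", "c", "d"], pos, pitch=1.0,
                         allow_colocated=True)
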