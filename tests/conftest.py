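import numpy as np
import pytest

from gliomafit import PhantomSpec, simulate_ground_truth
from gliomafit.geometry import BrainGeometry, Grid3D


@pytest.fixture(scope="session")
def default_phantom():
    """The default noiseless phantom series plus its density history."""
    spec = PhantomSpec()
    series, history = simulate_ground_truth(spec)
    return spec, series, history


@pytest.fixture()
def small_geometry():
    """A 16x16x8 all-brain geometry with a tiny central ventricle."""
    grid = Grid3D((16, 16, 8))
    brain = np.ones(grid.shape, dtype=bool)
    vent = np.zeros(grid.shape, dtype=bool)
    vent[7:9, 7:9, 3:5] = True
    return BrainGeometry(grid=grid, brain_mask=brain, ventricle_mask=vent)
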