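import logging

import numpy as np
import pytest

import lesioncov as lc
from lesioncov import synth as sy

logging.getLogger("lesioncov").setLevel(logging.ERROR)


def line_grid(n: int) -> lc.VoxelGrid:
    """Degenerate n x 1 x 1 grid: handy for feeding arbitrary value vectors
    through BrainMap-based APIs."""
    shape = (n, 1, 1)
    return lc.VoxelGrid(shape, (1.0, 1.0, 1.0), masks={"m": np.ones(shape, bool)})


def line_map(values) -> lc.BrainMap:
    values = np.asarray(values, dtype=float)
    return lc.BrainMap(line_grid(values.size), "m", values)


@pytest.fixture(scope="session")
def truth():
    """Default synthetic ground truth (24^3 grid, 4 mm voxels, k=3)."""
    return sy.make_truth(seed=1)


@pytest.fixture(scope="session")
def cohort(truth):
    """Default 240-subject lesion cohort drawn from ``truth``."""
    return sy.sample_lesions(truth, n=240, seed=2)


@pytest.fixture(scope="session")
def stack240(truth, cohort):
    return lc.stack([lc.fold_to_left(m) for m in cohort])


@pytest.fixture(scope="session")
def decomp(stack240):
    return lc.decompose(stack240, 3, seed=5)


@pytest.fixture(scope="session")
def smooth_cortex_map(truth):
    """A smooth scalar field on the cortex shell (white noise at 8 mm FWHM)."""
    g = truth.grid
    rng = np.random.default_rng(42)
    noise = lc.BrainMap(g, "cortex", rng.standard_normal(g.n_voxels("cortex")))
    return lc.smooth(noise, 8.0)
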