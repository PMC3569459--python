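import numpy as np
import pandas as pd
import pytest

from bioregionize.predictors import ClimateGrid
from bioregionize.synthetic import WorldConfig, make_world


@pytest.fixture(scope="session")
def small_world():
    """A quick 2-region world with fully detectable species."""
    return make_world(WorldConfig(n_rows=6, n_cols=8, n_regions=2, n_species=15,
                                  niche_width=0.15, detectability=1.0, seed=11))


@pytest.fixture()
def line_grid():
    """Three pixels on a line with one variable running 0..10."""
    coords = pd.DataFrame({"row": [0, 0, 0], "col": [0, 1, 2]},
                          index=pd.Index([0, 1, 2], name="pixel"))
    return ClimateGrid([0, 1, 2], coords, ["x"], np.array([[0.0], [5.0], [10.0]]))


def grid_from(values, var_names=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    coords = pd.DataFrame({"row": np.zeros(n, int), "col": np.arange(n)},
                          index=pd.Index(range(n), name="pixel"))
    names = var_names or [f"v{j}" for j in range(values.shape[1])]
    return ClimateGrid(list(range(n)), coords, names, values)
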