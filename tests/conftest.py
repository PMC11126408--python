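import numpy as np
import pytest

from ginet import Grid, SceneParams, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_scene():
    """A compact default-parameter scene shared by read-only tests."""
    return generate_scene(SceneParams(seed=11, n_rows=120, n_cols=130))


def grid_of(values, cell_size=30.0, **kw) -> Grid:
    return Grid(values=np.asarray(values), cell_size=cell_size, **kw)
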