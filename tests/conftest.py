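import numpy as np
import pytest

from velflow import GridGeometry


@pytest.fixture
def geom2d() -> GridGeometry:
    return GridGeometry((24, 20), (1.0, 1.5), (0.0, -3.0))


@pytest.fixture
def geom3d() -> GridGeometry:
    return GridGeometry((16, 16, 16), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
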