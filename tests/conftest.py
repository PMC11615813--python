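import numpy as np
import pytest

from rsomvasc.io import Image2D, PipelineConfig
from rsomvasc.phantom import PhantomSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def default_config():
    return PipelineConfig()


@pytest.fixture
def small_phantom_spec():
    """Compact 3D phantom spec used by end-to-end tests (fast to embed)."""
    return PhantomSpec(nx=192, ny=200, nz=230, n_trunks=8, wall_radius_um=1500.0)


def make_image(data, pixel_size=(20.0, 20.0)):
    return Image2D(data=np.asarray(data, dtype=np.float64), pixel_size=pixel_size)
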