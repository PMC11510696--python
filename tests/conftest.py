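import numpy as np
import pytest

from penetrakit.imaging_core import CalibratedImage
from penetrakit.synthetic_data import DrugSpec, cornea_spec, skin_spec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_image(pixels, scale=1.0, tissue="skin", **kw):
    return CalibratedImage(
        pixels=np.asarray(pixels, dtype=np.uint8),
        scale_um_per_px=scale,
        tissue=tissue,
        **kw,
    )


@pytest.fixture
def small_skin_spec():
    """Compact skin section: fast to render, same structure as the default."""
    return skin_spec(height_px=160, width_px=200, surface_row_px=40, sct_um=25.0)


@pytest.fixture
def small_cornea_spec():
    return cornea_spec(height_px=160, width_px=200, surface_row_px=40)


@pytest.fixture
def default_drug():
    return DrugSpec(amplitude=160.0, true_depth_um=50.0)
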