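import numpy as np
import pytest

from pivotyield import FieldSpec, RasterGrid
from pivotyield.scene import BAND_NAMES, MultispectralScene


@pytest.fixture
def small_spec():
    """A small pivot field: 60 m radius, 5 m cells (~24x24 grid)."""
    return FieldSpec(center_x=0.0, center_y=0.0, radius=60.0, pixel_size=5.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_grid(values, mask=None, pixel=10.0, x0=0.0, y0=None, units=""):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.isfinite(values)
    if y0 is None:
        y0 = values.shape[0] * pixel
    return RasterGrid(values, mask, x0, y0, pixel, units)


def make_scene(band_values, shape=(8, 8), pixel=30.0, **meta):
    """Build a scene from per-band constants or arrays."""
    bands = {}
    for name in BAND_NAMES:
        v = band_values[name]
        arr = np.full(shape, float(v)) if np.isscalar(v) else np.asarray(v, dtype=float)
        bands[name] = make_grid(arr, mask=np.ones(arr.shape, dtype=bool), pixel=pixel)
    return MultispectralScene(bands, **meta)
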