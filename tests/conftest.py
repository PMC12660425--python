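import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pldvol.mask import LiverMask
from pldvol.phantom import Ellipsoid, PhantomSpec

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_box_mask(ml_mm=120, ap_mm=150, cc_mm=200, spacing=(1.0, 1.0, 5.0), margin=(5, 5, 2)):
    """Axis-aligned solid box with the given physical extents."""
    dx, dy, dz = spacing
    nvox = (round(ml_mm / dx), round(ap_mm / dy), round(cc_mm / dz))
    shape = tuple(n + 2 * m for n, m in zip(nvox, margin))
    data = np.zeros(shape, dtype=bool)
    data[
        margin[0] : margin[0] + nvox[0],
        margin[1] : margin[1] + nvox[1],
        margin[2] : margin[2] + nvox[2],
    ] = True
    return LiverMask(data, spacing)


@pytest.fixture
def box_mask():
    """120 × 150 × 200 mm (ML × AP × CC) solid box at (1, 1, 5) mm voxels."""
    return make_box_mask()


#: Coarse, small-grid phantom family for fast simulation tests.
SMALL_SPEC = PhantomSpec(
    grid_shape=(120, 80, 72),
    spacing=(3.0, 3.0, 5.0),
    right_lobe=Ellipsoid((230.0, 120.0, 180.0), (65.0, 70.0, 100.0)),
    left_lobe=Ellipsoid((125.0, 110.0, 170.0), (55.0, 60.0, 85.0)),
    n_cysts=6,
    cyst_radius_mm=(8.0, 20.0),
)
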