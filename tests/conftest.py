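import numpy as np
import pytest

from aortiq import morphometry as M
from aortiq.phantoms import (
    GeometryPhantomSpec,
    gaussian_bulge,
    make_geometry_phantom,
)

# bulged candy-cane used by several morphometry tests: tube radius 14 mm with a
# +3 mm Gaussian radius bulge at mid-S1 (arc length 36 mm), so the true maximal
# mean diameter in S1 is 34 mm at the apex
BULGE_CENTER_MM = 36.0
BULGE_APEX_DIAMETER_MM = 34.0


@pytest.fixture(scope="session")
def cane():
    spec = GeometryPhantomSpec(
        ascending_curvature_radius_mm=45.9,
        ascending_tube_radius_mm=14.0,
        descending_length_mm=80.0,
        voxel_size_mm=1.0,
        tilt_deg=12.0,
        radius_profile=gaussian_bulge(BULGE_CENTER_MM, 3.0 / 14.0, 12.0),
        noise=0.0,
        seed=1,
    )
    mask, truth = make_geometry_phantom(spec)
    return spec, mask, truth


@pytest.fixture(scope="session")
def cane_centerline(cane):
    _, mask, truth = cane
    return M.extract_centerline(mask, endpoints_mm=truth.endpoints_mm)


@pytest.fixture(scope="session")
def noisy_cane():
    spec = GeometryPhantomSpec(
        ascending_curvature_radius_mm=40.0,
        ascending_tube_radius_mm=12.0,
        descending_length_mm=60.0,
        voxel_size_mm=1.0,
        tilt_deg=12.0,
        noise=0.4,
        seed=2,
    )
    mask, truth = make_geometry_phantom(spec)
    return spec, mask, truth


@pytest.fixture
def straight_centerline():
    z = np.arange(0.0, 401.0)
    return M.Centerline(np.column_stack([np.zeros_like(z), np.zeros_like(z), z]))
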