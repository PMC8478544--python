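import numpy as np
import pytest

from aortamorph import (
    interpolate_roi,
    phantom_contours,
    segment_plaques,
    segment_wall_lumen,
)
from aortamorph.phantom import PhantomSpec, PlaqueSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_spec(**kw) -> PhantomSpec:
    """A compact straight-tube phantom used throughout the unit tests."""
    defaults = dict(
        shape=(64, 48, 48),
        lumen_radius=0.103,
        wall_thickness=0.031,
        axial_margin=0.06,
        plaques=[PlaqueSpec(angle_deg=0.0, axial_center_mm=0.26, axial_span_mm=0.3, depth_mm=0.053)],
        seed=7,
    )
    defaults.update(kw)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def small_phantom():
    spec = small_spec()
    volume, truth = generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def small_pipeline(small_phantom):
    """Full segmentation of the small phantom, shared across tests."""
    spec, volume, truth = small_phantom
    roi = interpolate_roi(phantom_contours(spec), volume.shape, volume.voxel_size)
    wall_lumen = segment_wall_lumen(volume, roi, keep_intermediates=True)
    plaques = segment_plaques(volume, wall_lumen)
    return spec, volume, truth, roi, wall_lumen, plaques
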