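import numpy as np
import pytest

from octamorph import (
    GrowthParams,
    grow_network,
    rasterize,
    skeletonize,
    radius_weighted_skeleton,
)


@pytest.fixture(scope="session")
def growth_256():
    """Desk-scale growth preset: 256 px raster of the 3 mm field."""
    return GrowthParams().scaled(256)


@pytest.fixture(scope="session")
def net_256(growth_256):
    return grow_network(growth_256, seed=42)


@pytest.fixture(scope="session")
def raster_256(net_256):
    return rasterize(net_256, noise_sigma=0.0)


@pytest.fixture(scope="session")
def skel_256(net_256, raster_256):
    sk = skeletonize(raster_256.vessel_mask)
    return radius_weighted_skeleton(
        raster_256.vessel_mask, sk, net_256.pixel_pitch_um
    )


def random_blob_mask(rng: np.random.Generator, size: int = 96) -> np.ndarray:
    """Random multi-component blob mask for skeleton stress tests."""
    from scipy import ndimage as ndi

    field = ndi.gaussian_filter(rng.standard_normal((size, size)), 3.0)
    return field > np.percentile(field, 75)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * (a & b).sum() / max(a.sum() + b.sum(), 1)
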