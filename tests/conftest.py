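import math

import numpy as np
import pytest

from choroquant.phantom import PhantomParams, generate_phantom
from choroquant.scan_model import ScanGeometry


@pytest.fixture(scope="session")
def small_geometry() -> ScanGeometry:
    """Reduced radial layout (6 spokes × 30°) that keeps the half-circle
    tiling invariant while staying fast enough for unit tests."""
    return ScanGeometry(
        n_radials=6, angle_step_deg=30.0, n_alines=256, axial_px=128
    )


@pytest.fixture(scope="session")
def small_params(small_geometry) -> PhantomParams:
    return PhantomParams(
        geometry=small_geometry, blob_radius_px_range=(2.0, 5.0), seed=7
    )


@pytest.fixture(scope="session")
def small_phantom(small_params):
    return generate_phantom(small_params)


@pytest.fixture(scope="session")
def small_phantom_noiseless(small_params):
    import dataclasses

    params = dataclasses.replace(small_params, speckle_looks=math.inf)
    return generate_phantom(params)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
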