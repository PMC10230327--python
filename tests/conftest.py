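import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import clearwing as cw

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lam_visible():
    """Visible band at 1 nm sampling."""
    return cw.wavelength_grid(400.0, 700.0, 1.0)


@pytest.fixture(scope="session")
def lam_coarse():
    """Coarse band for FDTD runs."""
    return cw.wavelength_grid(400.0, 700.0, 20.0)


@pytest.fixture(scope="session")
def membrane_nipples():
    return cw.build_membrane("three-layer", "both")


@pytest.fixture(scope="session")
def membrane_flat():
    return cw.build_membrane("three-layer", "none")


@pytest.fixture(scope="session")
def membrane_nipples_R_T(membrane_nipples, lam_visible):
    R, T, A = cw.tmm_spectrum(membrane_nipples.stack, lam_visible)
    return R, T, A


@pytest.fixture(scope="session")
def chitin_slab_raster():
    """Planar 435 nm chitin slab rastered at dx = 5 nm."""
    return cw.StructureRaster(
        np.full((87, 4), 1.56), np.zeros((87, 4)), 5.0, name="chitin_slab"
    )
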