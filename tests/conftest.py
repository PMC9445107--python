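"""Shared fixtures: one phantom rasterization reused across the suite.

All test grids use the production voxel size (1.65 x 1.65 x 1.5 mm) on a
cropped 120^3 matrix that still contains the whole sphere ring, the lung
insert and the background VOIs; this keeps the suite fast without
changing any geometry that the metrics see.
"""

import pytest

import phantomiq as pq

TEST_SHAPE = (120, 120, 120)


@pytest.fixture(scope="session")
def nema_spec() -> pq.PhantomSpec:
    return pq.PhantomSpec.nema(ratio=4.0)


@pytest.fixture(scope="session")
def nema_truth(nema_spec) -> pq.Grid3D:
    return pq.rasterize_phantom(nema_spec, shape=TEST_SHAPE, supersampling=4)


@pytest.fixture(scope="session")
def blurred_455(nema_truth) -> pq.Grid3D:
    """Noiseless phantom blurred with a 4.55-mm Gaussian PSF (no positron blur)."""
    deg = pq.DegradationSpec(system_fwhm=4.55, nuclide=None, target_trues=None)
    return pq.blur_image(nema_truth, deg)


@pytest.fixture(scope="session")
def noisy_image(nema_truth) -> pq.Grid3D:
    """Phantom with 4.5-mm PSF blur and Poisson noise at 7.1e7 trues."""
    deg = pq.DegradationSpec(
        system_fwhm=4.5, nuclide=None, target_trues=7.1e7, seed=5
    )
    return pq.degrade_image(nema_truth, deg)


@pytest.fixture(scope="session")
def nema_spec_r8() -> pq.PhantomSpec:
    return pq.PhantomSpec.nema(ratio=8.0)


@pytest.fixture(scope="session")
def nema_truth_r8(nema_spec_r8) -> pq.Grid3D:
    return pq.rasterize_phantom(nema_spec_r8, shape=TEST_SHAPE, supersampling=4)
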