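import numpy as np
import pytest

from ernetics import synthkit
from ernetics.core import CellGeometry, ImagingConfig


@pytest.fixture(scope="session")
def clean_config():
    """Noiseless, blur-free acquisition for exact-value checks."""
    return ImagingConfig(pixel_size_nm=100, psf_sigma_nm=0, read_noise_sd=0,
                         shot_noise=False, frame_interval_s=4.0,
                         width_px=160, height_px=160)


@pytest.fixture(scope="session")
def study_config():
    """SNR≈10 study conditions: 16x16 um field, diffraction-limited PSF,
    Poisson shot noise plus 2-photon read noise."""
    return ImagingConfig(pixel_size_nm=100, psf_sigma_nm=100,
                         read_noise_sd=2.0, frame_interval_s=4.0,
                         width_px=160, height_px=160)


@pytest.fixture(scope="session")
def geometry():
    return CellGeometry.boxed(16.0, 16.0, nucleus_radii_um=(4.0, 3.2))


@pytest.fixture(scope="session")
def base_graph():
    """Well-connected polygonal network on the 16x16 um field."""
    return synthkit.generate_er_graph(16.0, 16.0, 0.5, 0.0, seed=3)
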