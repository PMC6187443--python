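import numpy as np
import pytest

from holocyte import (
    OpticsParams,
    SensorModel,
    blue_led_optics,
    forward_hologram,
    make_background,
    make_phantom,
)


@pytest.fixture(scope="session")
def optics_64():
    return OpticsParams(465e-9, 0.875e-3, 2.2e-6, (64, 64))


@pytest.fixture(scope="session")
def optics_128():
    return blue_led_optics((128, 128))


@pytest.fixture(scope="session")
def optics_256():
    return blue_led_optics((256, 256))


@pytest.fixture(scope="session")
def background_256(optics_256):
    return make_background(optics_256)


@pytest.fixture(scope="session")
def sparse_phantom_256(optics_256):
    """A small field of well-separated cells on a 256-px grid."""
    return make_phantom(optics_256, 12, seed=7)


@pytest.fixture(scope="session")
def sparse_hologram_256(sparse_phantom_256):
    return forward_hologram(sparse_phantom_256)


def random_band_limited_field(params, seed, cutoff_fraction=0.6):
    """Random complex field with no evanescent content (for propagation
    property tests): white noise low-passed inside the propagating band."""
    rng = np.random.default_rng(seed)
    rows, cols = params.grid_shape
    spec = rng.normal(size=(rows, cols)) + 1j * rng.normal(size=(rows, cols))
    f_r = np.fft.fftfreq(rows, params.pixel_pitch)
    f_c = np.fft.fftfreq(cols, params.pixel_pitch)
    fr, fc = np.meshgrid(f_r, f_c, indexing="ij")
    band = (fr**2 + fc**2) < (cutoff_fraction / params.wavelength) ** 2
    spec = spec * band
    return np.fft.ifft2(spec)
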