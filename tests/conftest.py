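import numpy as np
import pytest

from qpiscreen import OpticalConfig


@pytest.fixture(scope="session")
def config() -> OpticalConfig:
    return OpticalConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def bandpass_phantom(config):
    """Smooth zero-mean phantom band-limited to the well-transferred band."""
    shape = (128, 128)
    rng = np.random.default_rng(7)
    spec = np.fft.fft2(rng.standard_normal(shape))
    fy = np.fft.fftfreq(shape[0], d=config.pixel_size_um)
    fx = np.fft.fftfreq(shape[1], d=config.pixel_size_um)
    UY, UX = np.meshgrid(fy, fx, indexing="ij")
    r = np.sqrt(UX**2 + UY**2)
    band = (r > 0.05) & (r < 0.35)
    phi = np.fft.ifft2(spec * band).real
    phi *= 0.4 / np.abs(phi).max()
    return phi
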