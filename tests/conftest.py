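import numpy as np
import pytest


@pytest.fixture(scope="session")
def disk_image():
    """Bright disk (value 1.0) of radius 20 at (48, 48) on a 0.1 background."""
    yy, xx = np.mgrid[0:96, 0:96]
    inside = (xx - 48) ** 2 + (yy - 48) ** 2 <= 20**2
    return np.where(inside, 1.0, 0.1)


@pytest.fixture(scope="session")
def noisy_disk(disk_image):
    """The disk at SNR 5 (noise sd = amplitude / 5), min-max normalized."""
    rng = np.random.default_rng(11)
    img = disk_image + rng.normal(0.0, (1.0 - 0.1) / 5.0, disk_image.shape)
    return (img - img.min()) / (img.max() - img.min())


@pytest.fixture(scope="session")
def ring_image():
    """Ring cell: dark nucleus r=6, bright cytoplasm r=14, dark background."""
    yy, xx = np.mgrid[0:96, 0:96]
    r = np.hypot(xx - 48, yy - 48)
    return np.where(r <= 6, 0.1, np.where(r <= 14, 1.0, 0.15))
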