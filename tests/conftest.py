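import numpy as np
import pytest

from symaxis import DetectorConfig, FixtureSpec, make_mirrored_image


@pytest.fixture
def config():
    return DetectorConfig()


@pytest.fixture(scope="session")
def vertical_phantom():
    """A mirrored phantom with a vertical (90 degree) axis."""
    img, truth = make_mirrored_image(
        FixtureSpec(kind="mirrored_image", seed=7, true_alpha=90.0)
    )
    return img, truth


@pytest.fixture(scope="session")
def blob_image():
    """A single high-contrast blob on a flat background."""
    size = 64
    rows, cols = np.mgrid[0:size, 0:size]
    img = 0.2 + 0.7 * np.exp(-(((rows - 30) ** 2 + (cols - 34) ** 2) / (2 * 4.0**2)))
    return np.round(img * 255).astype(np.uint8)
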