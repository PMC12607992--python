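import numpy as np
import pytest

from fiberorder import synth


@pytest.fixture(scope="session")
def small_dataset():
    """60 default-condition images, shared across tests that only read it."""
    return synth.generate_dataset(60, seed=606)


@pytest.fixture(scope="session")
def fast_config():
    """Cheap renderer config for tests that need many fresh images."""
    return synth.GeneratorConfig(
        image_size=64,
        n_fibers=(40, 80),
        fiber_length=(16.0, 58.0),
        fiber_thickness=(1.0, 2.0),
    )


def stripe_image(size: int = 128, angle_deg: float = 30.0, period: float = 8.0) -> np.ndarray:
    """Sinusoidal grating whose stripes run along ``angle_deg``."""
    yy, xx = np.mgrid[0:size, 0:size]
    t = np.deg2rad(angle_deg)
    phase = -np.sin(t) * xx + np.cos(t) * yy
    return 0.5 + 0.4 * np.sin(2 * np.pi * phase / period)
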