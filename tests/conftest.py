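import numpy as np
import pytest

from octhrombus.oct_io import PolarFrame


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def beer_lambert_frame(
    mu: float,
    n_alines: int = 4,
    n_depth: int = 2048,
    dz: float = 0.005,
    i0: float = 1000.0,
    speckle_rng=None,
) -> PolarFrame:
    """Homogeneous forward Beer-Lambert phantom, optional exponential speckle."""
    z = np.arange(n_depth) * dz
    line = i0 * np.exp(-2.0 * mu * z)
    intensity = np.tile(line, (n_alines, 1))
    if speckle_rng is not None:
        intensity = intensity * speckle_rng.exponential(1.0, intensity.shape)
    return PolarFrame(intensity=intensity, axial_pitch_mm=dz, catheter_offset=0)


@pytest.fixture
def beer_lambert():
    return beer_lambert_frame
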