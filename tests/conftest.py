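import numpy as np
import pytest

from crowdvol.volume_io import ImageVolume


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_volume(rng):
    """A 3x8x8 volume of random 8-bit-valued intensities."""
    return ImageVolume(rng.integers(0, 256, size=(3, 8, 8)).astype(float))
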