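import numpy as np
import pytest

from octava.core_io import EnFaceImage
from octava.synthdata import NoiseParams, simulate_eye


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_image():
    return EnFaceImage(np.full((64, 64), 100, dtype=np.uint8))


@pytest.fixture(scope="session")
def small_eye():
    """One noisy 10-frame synthetic eye at reduced field size (shared)."""
    return simulate_eye(NoiseParams(), n_frames=10, seed=7, field_px=128)


@pytest.fixture(scope="session")
def noiseless_eye():
    """Jitter-free, noise-free eye: frames identical to the clean render."""
    return simulate_eye(NoiseParams.noiseless(), n_frames=3, seed=7, field_px=128)
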