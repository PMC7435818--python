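import numpy as np
import pytest

from ieamsc import EnergySpectrum, GeneratorParams, generate_image


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def random_image(rng):
    """A small random RGB image (every gray level possible)."""
    return rng.integers(0, 256, size=(24, 32, 3), dtype=np.uint8)


@pytest.fixture
def tea_image():
    """One deterministic synthetic tea frame at mid fixation."""
    return generate_image(GeneratorParams(degree=0.5, seed=11))


def make_spectrum(luma=None, R=None, G=None, B=None):
    """Build a spectrum from explicit bin vectors (zeros elsewhere)."""
    def vec(v):
        out = np.zeros(256, dtype=np.int64)
        if v is not None:
            for h, c in v.items():
                out[h] = c
        return out

    return EnergySpectrum(
        counts_R=vec(R), counts_G=vec(G), counts_B=vec(B), counts_luma=vec(luma)
    )
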