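import numpy as np
import pytest

from mrfseg.synthetic_data import default_blob_phantom, default_potts_phantom


@pytest.fixture(scope="session")
def potts_phantom_s15():
    """64x64 three-class Potts phantom, noise std 15 (the suite instance)."""
    return default_potts_phantom(sigma=15.0, seed=42)


@pytest.fixture(scope="session")
def blob_phantom():
    """128x128 two-class blob phantom factory keyed by noise std."""
    cache = {}

    def make(sigma: float):
        if sigma not in cache:
            cache[sigma] = default_blob_phantom(sigma=sigma, seed=3)
        return cache[sigma]

    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
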