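import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gaussian_cloud(rng):
    """Small generic point cloud with no duplicate points."""
    return rng.normal(size=(60, 4))


@pytest.fixture
def plane_5d():
    """400 points exactly on a random 2-D plane through the origin in 5-D.

    Returns (X, latent) where latent are the generating 2-D coordinates.
    """
    rng = np.random.default_rng(3)
    latent = rng.uniform(size=(400, 2))
    basis = np.linalg.qr(rng.normal(size=(5, 2)))[0]
    return latent @ basis.T, latent
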