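import numpy as np
import pytest

from lesionseg.synthetic import PhantomParams, generate_phantom_pair
from lesionseg.volume_io import BinaryMask3D, Volume


@pytest.fixture(scope="session")
def phantom():
    """One deterministic 64-cube phantom subject shared across tests."""
    pair, gt, catalog = generate_phantom_pair(PhantomParams(seed=42))
    return pair, gt, catalog


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_mask(data, spacing=(1.0, 1.0, 1.0)):
    data = np.asarray(data)
    return BinaryMask3D(data, spacing, np.diag(list(spacing) + [1.0]))


def make_volume(data, spacing=(1.0, 1.0, 1.0), id=""):
    data = np.asarray(data, dtype=np.float32)
    return Volume(data, spacing, np.diag(list(spacing) + [1.0]), id=id)


@pytest.fixture()
def mask_factory():
    return make_mask


@pytest.fixture()
def volume_factory():
    return make_volume
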