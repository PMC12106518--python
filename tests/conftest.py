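import numpy as np
import pytest

from osteodamage.energy import DEFAULT_PARAMETERS


@pytest.fixture(scope="session")
def theta():
    """Implementation-default model parameters."""
    return DEFAULT_PARAMETERS


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_symmetric(rng, scale=0.01):
    """Random symmetric 3x3 strain-sized tensor."""
    raw = rng.normal(0.0, scale, (3, 3))
    return (raw + raw.T) / 2.0


def random_rotation(rng):
    """Haar-ish random rotation matrix via QR."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
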