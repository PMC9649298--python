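import numpy as np
import pytest

from mcunet.blocks import DropBlockConfig
from mcunet.model import ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Smallest full architecture that still exercises every module."""
    return ModelConfig(base_channels=4, dropblock=DropBlockConfig(3, 0.9))


def numeric_grad(f, x, eps=1e-6):
    """Central finite differences of scalar-valued f at array x."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp = x.copy()
        xp[idx] += eps
        xm = x.copy()
        xm[idx] -= eps
        g[idx] = (f(xp) - f(xm)) / (2 * eps)
    return g


@pytest.fixture
def num_grad():
    return numeric_grad
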