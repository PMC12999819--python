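import numpy as np
import pytest

from whorlnet import nn
from whorlnet.nn import Tensor


@pytest.fixture(autouse=True)
def _seed_init():
    nn.manual_seed(0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def numeric_grad(fn, x: np.ndarray, eps: float = 1e-2) -> np.ndarray:
    """Central-difference gradient of scalar fn w.r.t. x."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = fn()
        x[idx] = orig - eps
        fm = fn()
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return g


def check_grad(make_out, param_arrays, rtol=0.08, atol=5e-3):
    """Compare autodiff gradients of sum(out) against numeric gradients."""
    out = make_out()
    out.sum().backward()
    for arr, tensor in param_arrays:
        num = numeric_grad(lambda: float(make_out().data.sum()), arr)
        got = tensor.grad
        assert got is not None
        np.testing.assert_allclose(got, num, rtol=rtol, atol=atol)
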