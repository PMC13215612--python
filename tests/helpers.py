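"""Shared numeric oracles for the test suite."""

import numpy as np

from pepflow.nn import Tensor


def numeric_gradient(fn, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of a scalar function of an array."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    flat = x.reshape(-1)
    gflat = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = fn(x)
        flat[i] = orig - eps
        lo = fn(x)
        flat[i] = orig
        gflat[i] = (hi - lo) / (2 * eps)
    return g


def numeric_jacobian(fn, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference Jacobian of a vector function of a flat vector."""
    x = np.asarray(x, dtype=np.float64)
    y0 = fn(x)
    J = np.zeros((y0.size, x.size))
    for i in range(x.size):
        xp = x.copy()
        xp[i] += eps
        xm = x.copy()
        xm[i] -= eps
        J[:, i] = (fn(xp) - fn(xm)) / (2 * eps)
    return J


def autodiff_gradient(fn, x: np.ndarray) -> np.ndarray:
    """Gradient of a scalar Tensor-valued function via the engine."""
    t = Tensor(np.asarray(x, dtype=np.float64), requires_grad=True)
    out = fn(t)
    out.backward()
    return t.grad
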