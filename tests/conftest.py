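import numpy as np
import pytest

from phytofuse.syndata import generate_dataset


def finite_diff_grad(f, x, eps=1e-6):
    """Central finite-difference gradient of scalar f at numpy array x."""
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        xp, xm = x.copy(), x.copy()
        xp[i] += eps
        xm[i] -= eps
        g[i] = (f(xp) - f(xm)) / (2 * eps)
        it.iternext()
    return g


@pytest.fixture(scope="session")
def small_dataset():
    """10 samples (2 per class), no planted ambiguity."""
    samples, manifest = generate_dataset(2, seed=7)
    return samples, manifest


@pytest.fixture(scope="session")
def ambiguous_dataset():
    """Confusability 0.5 dataset used by several modules."""
    samples, manifest = generate_dataset(6, seed=11, confusability=0.5)
    return samples, manifest
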