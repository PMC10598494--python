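import numpy as np
import pytest

from ctmonitor import synthgen as sg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def glyph_sequences():
    """Five 20-frame 32x32 moving-glyph sequences (desk-scale)."""
    return sg.generate_moving_glyphs(5, n_frames=20, size=32, seed=42)


@pytest.fixture(scope="session")
def small_phantom():
    return sg.generate_ct_phantom((32, 32, 32), seed=7)


@pytest.fixture(scope="session")
def nodule_phantom():
    return sg.generate_ct_phantom((32, 32, 32), with_nodule=True, seed=7)


def numeric_grad(f, x, eps=1e-6):
    """Central-difference gradient of scalar f at array x."""
    x = x.astype(float)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f(x)
        x[idx] = orig - eps
        fm = f(x)
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
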