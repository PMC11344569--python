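import numpy as np
import pytest

from dtivar.synthdata import (default_gradient_table, minimal_gradient_table,
                              two_roi_phantom, generate_dwi)

WM_LAMBDA = np.array([1.7e-3, 0.3e-3, 0.3e-3])


def fa_of(lam: np.ndarray) -> float:
    lam = np.asarray(lam, dtype=float)
    md = lam.mean()
    den = np.sqrt((lam ** 2).sum())
    if den == 0:
        return 0.0
    return float(np.sqrt(1.5) * np.sqrt(((lam - md) ** 2).sum()) / den)


@pytest.fixture(scope="session")
def grad6():
    return minimal_gradient_table()


@pytest.fixture(scope="session")
def grad32():
    return default_gradient_table()


@pytest.fixture(scope="session")
def noiseless_phantom(grad32):
    """Two-ROI noiseless phantom with its labels and ground-truth tensors."""
    spec = two_roi_phantom(sigma=0.0, noise_model="none")
    return generate_dwi(spec, grad32)
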