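import numpy as np
import pytest

from petmr_qa.acr import ACRGeometryConfig
from petmr_qa.phantoms import ACRSeriesSpec, gen_acr_phantom


@pytest.fixture(scope="session")
def acr_default():
    """Noiseless ACR-like phantom at default truth, shared across tests."""
    vol, truth = gen_acr_phantom(ACRSeriesSpec())
    return vol, truth, ACRGeometryConfig.default()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def radial_quadratic_field(max_shift_mm: float, r_max_mm: float = 117.0):
    """Smooth radial displacement field growing quadratically from the
    isocentre — the shape of typical gradient-nonlinearity distortion."""

    def field(p: np.ndarray) -> np.ndarray:
        r = np.linalg.norm(p, axis=1, keepdims=True)
        mag = max_shift_mm * (r / r_max_mm) ** 2
        return np.where(r > 1e-9, mag * p / np.maximum(r, 1e-9), 0.0)

    return field
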