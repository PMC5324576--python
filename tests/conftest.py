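import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def analytic_gaussian_entropy_bits(cov: np.ndarray) -> float:
    """Closed-form differential entropy of a Gaussian, independent route."""
    cov = np.atleast_2d(cov)
    k = cov.shape[0]
    sign, logdet = np.linalg.slogdet(cov)
    assert sign > 0
    return 0.5 * (k * np.log(2 * np.pi * np.e) + logdet) / np.log(2)


def analytic_gaussian_mi_bits(r: float) -> float:
    """MI of a bivariate Gaussian with correlation r."""
    return -0.5 * np.log2(1.0 - r * r)
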