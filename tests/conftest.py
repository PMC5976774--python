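import numpy as np
import pytest

from cpca.core import CovariancePair, DataMatrix


def random_cov_pair(rng: np.random.Generator, d: int, n: int = 200,
                    m: int = 200) -> CovariancePair:
    """A generic random PSD covariance pair (Wishart-style, O(1) scale)."""
    ax = rng.standard_normal((d, d))
    ay = rng.standard_normal((d, d))
    return CovariancePair(ax @ ax.T / d, ay @ ay.T / d, n, m)


def random_dataset_pair(rng: np.random.Generator, n: int, m: int,
                        d: int) -> tuple[DataMatrix, DataMatrix]:
    """Random target/background data with mildly anisotropic covariance."""
    scales = rng.uniform(0.5, 2.0, size=d)
    x = rng.standard_normal((n, d)) * scales + rng.normal(0, 1, d)
    y = rng.standard_normal((m, d)) * rng.uniform(0.5, 2.0, size=d)
    return DataMatrix.from_array(x), DataMatrix.from_array(y)


def angle_to_subspace(v: np.ndarray, basis: np.ndarray) -> float:
    """Angle (radians) between a vector and the span of an orthonormal basis."""
    basis = np.atleast_2d(basis)
    if basis.shape[0] < basis.shape[1]:
        basis = basis.T
    proj = basis @ (basis.T @ v)
    c = np.linalg.norm(proj) / np.linalg.norm(v)
    return float(np.arccos(min(1.0, c)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
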