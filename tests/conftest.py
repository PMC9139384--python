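import numpy as np
import pytest


def random_spd(d: int, rng, scale: float = 1.0) -> np.ndarray:
    """Well-conditioned random SPD matrix: A A^T + d*I scaled down."""
    A = rng.standard_normal((d, d))
    M = A @ A.T + d * np.eye(d)
    return scale * M / d


def random_spd_set(d: int, n: int, seed: int, scale: float = 1.0) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    return [random_spd(d, rng, scale) for _ in range(n)]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
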