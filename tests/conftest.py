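import numpy as np
import pytest

from isingmiss import IsingMatrix


@pytest.fixture
def toy3() -> IsingMatrix:
    """Small J=3 network with one negative and two positive couplings."""
    return IsingMatrix(np.array([
        [0.0, 0.8, -0.6],
        [0.8, 0.0, 0.5],
        [-0.6, 0.5, 0.0],
    ]))


def random_ising(J: int, rng: np.random.Generator, scale: float = 1.0) -> IsingMatrix:
    """Random symmetric matrix with entries uniform on [-scale, scale]."""
    a = rng.uniform(-scale, scale, size=(J, J))
    return IsingMatrix((a + a.T) / 2.0)
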