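import numpy as np
import pytest

from arcgp.kernels import MarkerMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_markers(rng):
    """8 lines x 20 features, continuous (already centered-ish)."""
    X = rng.standard_normal((8, 20))
    return MarkerMatrix(
        X, [f"L{i}" for i in range(8)], [f"f{j}" for j in range(20)], scaled=True
    )


@pytest.fixture
def dosage_markers(rng):
    """10 lines x 50 biallelic dosages."""
    X = rng.binomial(2, 0.4, size=(10, 50)).astype(float)
    return MarkerMatrix(X, [f"L{i}" for i in range(10)], [f"m{j}" for j in range(50)])
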