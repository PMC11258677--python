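import numpy as np
import pytest

from canopygeo import VariogramModel, build_weights


@pytest.fixture
def lattice20():
    """20 x 20 unit lattice coordinates (n = 400), row-major."""
    xx, yy = np.meshgrid(np.arange(20.0), np.arange(20.0))
    return np.column_stack([xx.ravel(), yy.ravel()])


@pytest.fixture
def rook_weights20(lattice20):
    """Row-standardized rook contiguity on the 20 x 20 lattice."""
    return build_weights(lattice20, scheme="band", param=1.0)


@pytest.fixture
def exp_model():
    """A short-range exponential model on cover scale (sill 0.009)."""
    return VariogramModel("exponential", 0.001, 0.008, 8.0)


@pytest.fixture
def reference_model():
    """The reference exponential model of the emulated study area."""
    return VariogramModel("exponential", 0.12e-2, 0.77e-2, 10_200.0)
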