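import numpy as np
import pytest

from sentipol import calibration
from sentipol.grids import DensityField2D, Grid1D, Grid2D
from sentipol.seir import CompartmentMasses


@pytest.fixture
def grid20() -> Grid1D:
    return Grid1D(20)


@pytest.fixture
def square20() -> Grid2D:
    return Grid2D(20, 20)


@pytest.fixture
def negative_mixture():
    """Shipped bimodal calibration of the negative-score marginal."""
    return calibration.negative_mixture()


@pytest.fixture
def positive_mixture():
    return calibration.positive_mixture()


@pytest.fixture
def initial_masses() -> CompartmentMasses:
    return calibration.initial_masses()


@pytest.fixture
def product_beta22(square20) -> DensityField2D:
    """Smooth unit-mass Beta(2,2) x Beta(2,2) density on the 20x20 grid."""
    from sentipol.equilibria import BetaSpec

    b = BetaSpec.from_shape(2.0, 2.0)
    return DensityField2D(
        square20,
        np.outer(b.cell_averages(square20.axis_plus), b.cell_averages(square20.axis_minus)),
    )
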