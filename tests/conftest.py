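import numpy as np
import pytest

from qpcrfit import (
    AmplificationCurve,
    DilutionSeries,
    ExpModelParams,
    exp_model_value,
)
from qpcrfit.simulate import CurveDesign, default_point_design


@pytest.fixture
def design():
    """Default 9-point / 3-curve design (E=1.85, sigma_y=2.4, D=2)."""
    return default_point_design()


@pytest.fixture
def noiseless_points(design):
    return design.points(design.exact_values())


@pytest.fixture
def noisy_points(design):
    rng = np.random.default_rng(1234)
    y = design.exact_values() + rng.normal(0.0, design.sigma_y, 9)
    return design.points(y)


@pytest.fixture
def curve_design():
    return CurveDesign(sigma_y=2.4)


def make_exponential_series(y0=0.04, E=1.85, D=2.0, n_curves=3, n_cycles=40):
    """Noiseless exponential dilution series over integer cycles 1..n_cycles."""
    params = ExpModelParams(y0=y0, E=E, D=D)
    cycles = np.arange(1, n_cycles + 1)
    curves = [
        AmplificationCurve(
            well_id=f"W{j}",
            dilution_exponent=j,
            cycles=cycles,
            fluorescence=np.asarray(exp_model_value(params, cycles, j)),
        )
        for j in range(n_curves)
    ]
    return DilutionSeries(curves=curves, dilution_factor=D)


@pytest.fixture
def exponential_series():
    return make_exponential_series()
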