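import numpy as np
import pytest

from vhi import DoseResponseSeries, MechanicsSeries, logistic_response

LOG_GRID = np.arange(-9.0, -5.75, 0.5)  # 7 half-log steps, 1e-9 .. 1e-6 M


def make_logistic_series(lower, upper, log_ec50, noise_sd=0.0, rng=None,
                         animal_id="a1", bed="skeletal", x=LOG_GRID):
    y = logistic_response(x, lower, upper, log_ec50)
    if noise_sd:
        y = y + rng.normal(0.0, noise_sd, size=y.size)
    return DoseResponseSeries(animal_id=animal_id, bed=bed,
                              concentrations=10.0 ** np.asarray(x), responses=y)


def make_mechanics_series(pressures, inner, outer, animal_id="a1", bed="skeletal"):
    return MechanicsSeries(animal_id=animal_id, bed=bed, pressures=pressures,
                           inner_diameters=inner, outer_diameters=outer)


@pytest.fixture
def rng():
    return np.random.default_rng(20230125)
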