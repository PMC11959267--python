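import numpy as np
import pytest

import lastrain as ls
from lastrain.synthetic import CohortSpec, generate_cohort, make_base_shape


@pytest.fixture(scope="session")
def small_shape():
    """Coarse LA-like base anatomy (162 vertices) shared across tests."""
    return make_base_shape(subdivisions=2, radius_mm=30.0)


@pytest.fixture(scope="session")
def sphere_shape():
    return make_base_shape(subdivisions=3, radius_mm=20.0, sphere=True)


@pytest.fixture(scope="session")
def plateau_sequence(small_shape):
    params = ls.MotionModelParams(reservoir_amplitude=21.0,
                                  contractile_fraction=0.5, n_frames=10)
    return ls.generate_mesh_sequence(params, small_shape)


@pytest.fixture(scope="session")
def analytic_cohort():
    """Fast analytic-mode cohort with the default group effects."""
    spec = CohortSpec(n_per_group=10, mode="analytic", seed=11)
    table, _ = generate_cohort(spec)
    return table


@pytest.fixture(scope="session")
def piecewise_linear_curve():
    """Constructed level-off fixture: rise 0->25 on [0, 0.4], fall to 12
    on [0.4, 0.7], flat to 0.8, fall to 0 at the cycle end."""
    t = np.arange(10) / 10
    s = np.interp(t, [0.0, 0.4, 0.7, 0.8, 1.0], [0.0, 25.0, 12.0, 12.0, 0.0])
    return s, t
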