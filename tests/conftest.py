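import numpy as np
import pytest

from stepscale import (
    StudyArea,
    generate_resource_layer,
    make_resource_central_place_kernel,
)


@pytest.fixture(scope="session")
def resource_20():
    """Smooth 20x20 synthetic resource layer in [0, 1]."""
    return generate_resource_layer(20, 20, smoothness=4.0, seed=2)


@pytest.fixture(scope="session")
def home_range_kernel_20(resource_20):
    """Resource + central-place kernel on the 20x20 landscape."""
    return make_resource_central_place_kernel(
        resource_20, (10.0, 10.0), lam=0.2, beta_r=1.5, beta_c=0.2
    )


@pytest.fixture(scope="session")
def area_3x3():
    return StudyArea(3, 3)


@pytest.fixture
def two_state_chain():
    """2-state Markov chain P = [[1-p, q], [p, 1-q]], p=0.3, q=0.1.

    Stationary distribution (q, p) / (p + q) = (0.25, 0.75).
    """
    p, q = 0.3, 0.1
    P = np.array([[1 - p, q], [p, 1 - q]])
    return P, np.array([0.25, 0.75])
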