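import numpy as np
import pytest

from specbind import BindingParameters, BindingPoint


def hill_points(K_H, n_H, g, n=25, occupancy=(0.05, 0.95)):
    """Exact binding points on the Hill isotherm, spanning the given
    fractional-occupancy range (inverts nu(L_free) analytically)."""
    alpha = np.linspace(*occupancy, n)
    L_free = (alpha / (1.0 - alpha) / K_H) ** (1.0 / n_H)
    return [
        BindingPoint(nu=float(a * g), L_free=float(L)) for a, L in zip(alpha, L_free)
    ]


@pytest.fixture
def single_site_params():
    return BindingParameters.single_site(6778.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20230913)
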