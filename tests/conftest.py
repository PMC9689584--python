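import numpy as np
import pytest

from ctbsi.density import DensityFitConfig
from ctbsi.experiments import cycle_model, make_model, two_ig_mixture
from ctbsi.model_core import ExponentialDwell, InverseGaussianDwell


@pytest.fixture(scope="session")
def fig4_model():
    """Four-state cycle: phi_A = phi_D = IG(1,5), phi_B = phi_C = IG(3,2)."""
    return make_model("fig4_4state")


@pytest.fixture(scope="session")
def two_state_model():
    return make_model("fig3_2state")


@pytest.fixture(scope="session")
def exp_two_cycle():
    """Two-state cycle with unit-mean exponential dwells (entropy rate 1 nat)."""
    return cycle_model([ExponentialDwell(1.0), ExponentialDwell(1.0)])


@pytest.fixture(scope="session")
def mixture_truth():
    return two_ig_mixture()


@pytest.fixture(scope="session")
def tiny_config():
    """Small, fast neural-fit configuration for unit tests."""
    return DensityFitConfig(layers=3, width=5, epochs=150, seeds=(0,),
                            integration_grid=256)


def random_cycle_model(rng: np.random.Generator):
    """A random even-length binary cycle with random inverse-Gaussian dwells."""
    m = int(rng.choice([2, 4, 6, 8]))
    dwells = [
        InverseGaussianDwell(float(rng.uniform(0.5, 4.0)),
                             float(rng.uniform(0.5, 5.0)))
        for _ in range(m)
    ]
    return cycle_model(dwells)
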