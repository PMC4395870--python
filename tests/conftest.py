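import numpy as np
import pytest

from fretsplice.cohort import default_calibration
from fretsplice.synthetic import ForwardModelParams, generate_fret_stack, make_embryo_scene


@pytest.fixture(scope="session")
def noiseless_params():
    return ForwardModelParams(noise="none", alpha=0.3, delta=0.15)


@pytest.fixture(scope="session")
def poisson_params():
    return ForwardModelParams(noise="poisson")


@pytest.fixture(scope="session")
def scene():
    return make_embryo_scene(seed=1)


@pytest.fixture(scope="session")
def noiseless_run(scene, noiseless_params):
    """(stack, truth_E, calibration) for the noiseless default embryo."""
    stack, truth = generate_fret_stack(scene, noiseless_params, n_frames=1)
    return stack, truth, default_calibration(noiseless_params, bin_factor=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
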