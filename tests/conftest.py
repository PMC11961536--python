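import numpy as np
import pytest
from hypothesis import settings

from qcmdlysis import SimParams, simulate_experiment

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def control_exp_nf():
    """Noise-free control experiment (deterministic latent signal only)."""
    return simulate_experiment(SimParams.control(noise_sd_f=0.0, noise_sd_D=0.0))


@pytest.fixture(scope="session")
def infectious_exp_nf():
    """Noise-free infectious experiment at the highest titer."""
    return simulate_experiment(
        SimParams.infectious(titer=8e7, noise_sd_f=0.0, noise_sd_D=0.0)
    )


@pytest.fixture(scope="session")
def noisy_control_exp():
    return simulate_experiment(SimParams.control(seed=7))


@pytest.fixture()
def uniform_grid():
    return np.arange(0.0, 400.0, 0.5)
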