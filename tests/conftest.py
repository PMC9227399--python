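import numpy as np
import pytest

import zaipp
from zaipp.kinetics import param_names, params_to_dict


@pytest.fixture(scope="session")
def m1_continuous():
    return zaipp.scenario_truth("model1_continuous")


@pytest.fixture(scope="session")
def m1_pulse():
    return zaipp.scenario_truth("model1_pulse")


@pytest.fixture(scope="session")
def m2_continuous():
    return zaipp.scenario_truth("model2_continuous")


@pytest.fixture(scope="session")
def m2_pulse():
    return zaipp.scenario_truth("model2_pulse")


def truth_dict(za, ag):
    return params_to_dict(za, ag)


def fitspec_fixing(model_id, free, truth, **controls):
    """FitSpec freeing `free` and pinning every other parameter at truth."""
    fixed = {n: truth[n] for n in param_names(model_id) if n not in free}
    init = {n: truth[n] * 1.2 for n in free}
    return zaipp.FitSpec(model_id, tuple(free), fixed, init, **controls)


@pytest.fixture(scope="session")
def noiseless_m1c_obs(m1_continuous):
    za, ag, design = m1_continuous
    return zaipp.generate_observations(1, za, ag, design, sigma_Z=0.0, sigma_G=0.0, seed=0)


def rand_za(rng):
    """Random but well-scaled ZA kinetic block for property tests."""
    lo, hi = np.log(1e-3), np.log(5.0)
    kZY, kXY, kYZ, kXZ = np.exp(rng.uniform(lo, hi, 4))
    rho = rng.uniform(1.0, 50.0)
    return zaipp.ZAKineticParams(kZY=kZY, kXY=kXY, kYZ=kYZ, rhoZY=rho, kXZ=kXZ)
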