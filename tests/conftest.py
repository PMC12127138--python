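import numpy as np
import pytest

from deadrecovery import (
    DEFAULT_DESIGN,
    ParamSet,
    StudyDesign,
    simulate_dr,
    simulate_joint,
)

SMALL_DESIGN = StudyDesign(T=5, releases=(40, 40, 40, 40, 0))


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def dr_params():
    return ParamSet(s=0.5, r=0.2)


@pytest.fixture
def joint_params():
    return ParamSet(s=0.5, r=0.2, p=0.6)


@pytest.fixture
def dr_data(rng, dr_params):
    """One default-design dead-recovery dataset (700 individuals, T=8)."""
    return simulate_dr(dr_params, DEFAULT_DESIGN, rng)


@pytest.fixture
def joint_data(rng, joint_params):
    """One default-design joint dataset (700 individuals, T=8)."""
    return simulate_joint(joint_params, DEFAULT_DESIGN, rng)


@pytest.fixture
def small_dr_data(rng, dr_params):
    return simulate_dr(dr_params, SMALL_DESIGN, rng)


@pytest.fixture
def small_joint_data(rng, joint_params):
    return simulate_joint(joint_params, SMALL_DESIGN, rng)
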