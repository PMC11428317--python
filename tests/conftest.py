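import pytest

from sprawlgait.body import default_andrias_plan
from sprawlgait.experiment import run_lateral_bending_experiment
from sprawlgait.gait import GaitParams, simulate


@pytest.fixture(scope="session")
def plan():
    return default_andrias_plan()


@pytest.fixture(scope="session")
def default_gait():
    return GaitParams()


@pytest.fixture(scope="session")
def moderate_traj(plan, default_gait):
    """Ten strides of the default (moderate-bending) gait at feasible speed."""
    return simulate(plan, default_gait, n_strides=10)


@pytest.fixture(scope="session")
def straight_traj(plan):
    """Five strides with no lateral bending (80-frame stride, as published)."""
    gait = GaitParams(bending_amplitude=0.0, frames_per_stride=80)
    return simulate(plan, gait, n_strides=5)


@pytest.fixture(scope="session")
def comparison_table(plan):
    return run_lateral_bending_experiment(default_andrias_plan())
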