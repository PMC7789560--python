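import numpy as np
import pytest

from reachsim.kinematics import ArmGeometry, JointPosture
from reachsim.tasks import build_target_grid, build_target_set


@pytest.fixture(scope="session")
def geometry():
    return ArmGeometry()


@pytest.fixture(scope="session")
def comfort():
    from reachsim.subject import DEFAULT_COMFORT

    return DEFAULT_COMFORT


@pytest.fixture(scope="session")
def grid(geometry):
    return build_target_grid(geometry)


@pytest.fixture(scope="session")
def whole_set(grid):
    return build_target_set(grid, "whole")


@pytest.fixture(scope="session")
def subset(grid):
    return build_target_set(grid, "subset")
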