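"""Shared fixtures: expensive model equilibrations are session-scoped."""

import numpy as np
import pytest

from calreg.cell_model import (
    DrugBlock,
    MinimalHiPSCCM,
    compute_target_calcium,
    limit_cycle_init,
)
from calreg.regulation import RegulationParams


@pytest.fixture(scope="session")
def model():
    return MinimalHiPSCCM()


@pytest.fixture(scope="session")
def default_init(model):
    """Default limit cycle state (n = 1, no drug), upstroke-aligned."""
    init = limit_cycle_init(model, 1.0, DrugBlock.none())
    assert not init.quiescent
    return init


@pytest.fixture(scope="session")
def c_star(model):
    """Target calcium: cycle-averaged cytosolic calcium of the default model."""
    return compute_target_calcium(model)


@pytest.fixture(scope="session")
def reg_params(c_star):
    return RegulationParams(c_target_mM=c_star)
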