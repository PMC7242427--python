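import numpy as np
import pytest

from memswell import (
    EllipsoidShape,
    MediumState,
    SimulationConfig,
    imm_rigidity,
    simulate_swelling,
)
from memswell.config import EQUILIBRIUM_SHAPES


@pytest.fixture(scope="session")
def resting_shape() -> EllipsoidShape:
    return EllipsoidShape(8.0, 2.0)


@pytest.fixture(scope="session")
def imm():
    return imm_rigidity()


@pytest.fixture(scope="session")
def equilibrium_shapes():
    """The six swollen-equilibrium shapes shipped with the fixtures."""
    return [EllipsoidShape(a, c) for _, a, c in EQUILIBRIUM_SHAPES]


def nacl_medium(c_in: float, c_out: float = 1.0, T: float = 310.0) -> MediumState:
    return MediumState.from_dict({"Na": (c_in, c_out), "Cl": (c_in, c_out)}, T=T)


@pytest.fixture(scope="session")
def linear_config(resting_shape, imm) -> SimulationConfig:
    """Weak-drive scenario staying within ~1.6% volume change: the
    stretch response remains on its linear branch (reversible regime)."""
    return SimulationConfig(
        shape=resting_shape,
        medium=nacl_medium(2.5),
        rigidity=imm,
        t_span=5e4,
    )


@pytest.fixture(scope="session")
def linear_traj(linear_config):
    return simulate_swelling(linear_config)


@pytest.fixture(scope="session")
def strong_config(resting_shape, imm) -> SimulationConfig:
    """30 mM hypertonic interior: osmotic drive beyond the disruption
    threshold of the membrane (irreversible/pathological regime)."""
    return SimulationConfig(
        shape=resting_shape,
        medium=nacl_medium(30.0),
        rigidity=imm,
        t_span=5e6,
    )


@pytest.fixture(scope="session")
def strong_traj(strong_config):
    return simulate_swelling(strong_config)
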