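import numpy as np
import pytest

from navpyr.energetics import EnergyModel
from navpyr.proteins import protein_topology
from navpyr.synthetic import (
    MiniChannelParams,
    make_docking_truth,
    make_mini_channel,
    make_toy_ligand,
    sensing_labels,
)


@pytest.fixture(scope="session")
def mini_channel():
    """(open, inactivated, annotation) toy channel, default geometry."""
    return make_mini_channel()


@pytest.fixture(scope="session")
def open_channel(mini_channel):
    return mini_channel[0]


@pytest.fixture(scope="session")
def inactivated_channel(mini_channel):
    return mini_channel[1]


@pytest.fixture(scope="session")
def annotation(mini_channel):
    return mini_channel[2]


@pytest.fixture(scope="session")
def vsm_channel():
    """Mini-channel with S4 voltage-sensing helices."""
    return make_mini_channel(MiniChannelParams(include_vsm=True))


@pytest.fixture(scope="session")
def ligand_type2():
    return make_toy_ligand("type2")


@pytest.fixture(scope="session")
def ligand_type1():
    return make_toy_ligand("type1")


@pytest.fixture(scope="session")
def model():
    return EnergyModel.default()


@pytest.fixture(scope="session")
def receptor_topology(open_channel):
    return protein_topology(open_channel)


@pytest.fixture(scope="session")
def sensing(open_channel):
    return sensing_labels()


@pytest.fixture(scope="session")
def truth(open_channel, inactivated_channel, ligand_type2):
    """Planted docking ground truth (fixed fixture seed)."""
    return make_docking_truth(
        open_channel, ligand_type2, seed=7, inactivated=inactivated_channel
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
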