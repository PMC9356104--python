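import numpy as np
import pytest

from logicscape.fixtures import fixture
from logicscape.landscape import EnergyLandscape
from logicscape.network import GRN
from logicscape.trees import Configuration, Leaf


@pytest.fixture(scope="session")
def toy():
    return fixture("toy")


@pytest.fixture(scope="session")
def mef_ipsc():
    return fixture("mef_ipsc")


@pytest.fixture(scope="session")
def pluripotency():
    return fixture("pluripotency")


@pytest.fixture
def activation_motif():
    """B -> A: A regulated by the activator B, B unregulated."""
    grn = GRN(("A", "B"), (("B", "A", 1),))
    config = Configuration.from_trees(grn, {"A": Leaf("B"), "B": None})
    return grn, config


@pytest.fixture
def mutual_activation_landscape():
    """T = (0, 1, 1, -2) for two mutually activating genes."""
    return EnergyLandscape(np.array([0.0, 1.0, 1.0, -2.0]), ("A", "B"))
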