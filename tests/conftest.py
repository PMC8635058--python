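import numpy as np
import pytest

from ambitopo.montage import Montage, build_neighbor_graph, make_standard_montage

#: 16-channel sub-cap used by reduced-scale simulations
REDUCED_CHANNELS = ("Fp1", "Fp2", "F3", "Fz", "F4", "C3", "Cz", "C4",
                    "T7", "T8", "P3", "Pz", "P4", "O1", "Oz", "O2")


@pytest.fixture(scope="session")
def montage31():
    return make_standard_montage()


@pytest.fixture(scope="session")
def graph31(montage31):
    return build_neighbor_graph(montage31)


@pytest.fixture(scope="session")
def montage16(montage31):
    return montage31.subset(REDUCED_CHANNELS)


@pytest.fixture(scope="session")
def graph16(montage16):
    return build_neighbor_graph(montage16, max_distance=0.6)


@pytest.fixture(scope="session")
def pair_montage():
    """Two mutually adjacent channels — the smallest legal montage."""
    m = Montage(("A", "B"), np.array([[0.0, 0.0], [0.3, 0.0]]))
    return m, build_neighbor_graph(m, max_distance=0.5)
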