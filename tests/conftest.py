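import numpy as np
import pytest

from wgdresolve.model import LossParams
from wgdresolve.pillars import JunctionModel, PillarSet
from wgdresolve.trees import LossTree


@pytest.fixture
def two_genome_tree():
    return LossTree.from_newick("(A:0.3,B:0.4):0.2;")


@pytest.fixture
def params():
    return LossParams(gamma=0.2, epsilon=0.6)


@pytest.fixture
def small_pillars():
    """Three pillars over two genomes with one double break."""
    obs = np.array([[0, 1], [1, 2], [2, 0]], dtype=np.int8)
    breaks = np.array([[False, True], [False, False]])
    return PillarSet(("A", "B"), ["a0", "a1", "a2"], obs, breaks)


@pytest.fixture
def small_junctions(small_pillars):
    return JunctionModel(0.01, small_pillars.double_breaks)
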