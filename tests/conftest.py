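import numpy as np
import pytest

from traitsignal import synthetic_data as syn
from traitsignal.phylo import parse_newick


@pytest.fixture(scope="session")
def tree64():
    """Fixed 64-tip Yule tree shared by the signal calibration tests."""
    return syn.simulate_tree(64, seed=12)


@pytest.fixture(scope="session")
def tree128():
    return syn.simulate_tree(128, seed=11)


@pytest.fixture
def balanced4():
    """4-tip balanced ultrametric tree with unit branches."""
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def star5():
    return parse_newick("(A:1,B:1,C:1,D:1,E:1);")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
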