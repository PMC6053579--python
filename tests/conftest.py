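import numpy as np
import pytest

from phylodispersal import PhyloTree
from phylodispersal.simulate import simulate_yule_tree


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); — ultrametric, depth 2."""
    return PhyloTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced_four_tip_tree():
    """((A,B),(C,D)) with unit branch lengths."""
    return PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def star_tree():
    return PhyloTree.from_newick("(A:1,B:1,C:1,D:1,E:1,F:1,G:1,H:1);")


@pytest.fixture
def yule_tree_20():
    return simulate_yule_tree(20, 1.0, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
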