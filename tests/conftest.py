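import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from nichebar.phylo import parse_newick
from nichebar.simulator import simulate_bd_tree


@pytest.fixture
def balanced_quartet():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def rng():
    return np.random.default_rng(20241)


def random_tree(rng, n_tips):
    """Random ultrametric pure-birth tree, deterministic given the rng state."""
    return simulate_bd_tree(n_tips, 1.0, 0.0, rng)
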