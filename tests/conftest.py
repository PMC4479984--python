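import numpy as np
import pytest

import pstoich as ps


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); — C = [[2,1,0],[1,2,0],[0,0,2]] in order A,B,C."""
    return ps.parse_newick("((A:1.0,B:1.0):1.0,C:2.0);")


@pytest.fixture
def star_tree():
    return ps.parse_newick("(A:1,B:1,C:1,D:1);")


@pytest.fixture
def rng():
    return np.random.default_rng(20150625)


def random_tree(n_tips, seed, unit_depth=True):
    return ps.simulate_tree(
        n_tips=n_tips, rng=np.random.default_rng(seed), unit_depth=unit_depth
    )
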