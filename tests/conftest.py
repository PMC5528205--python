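import numpy as np
import pandas as pd
import pytest

import commstruct as cs

#: four-tip reference tree used throughout:
#: A,B are sisters (pendant 1, stem 2); C,D are sisters (pendant 2, stem 1)
T1_NEWICK = "((A:1,B:1):2,(C:2,D:2):1);"


@pytest.fixture
def t1():
    return cs.parse_newick(T1_NEWICK)


@pytest.fixture
def t1_dm(t1):
    return t1.patristic_matrix()


@pytest.fixture
def star4():
    return cs.parse_newick("(A:1,B:1,C:1,D:1);")


@pytest.fixture
def community_df():
    return pd.DataFrame(
        {
            "plot": ["p1", "p1", "p1", "p2", "p2"],
            "species": ["A", "B", "C", "C", "D"],
            "abundance": [4.0, 2.0, 2.0, 1.0, 3.0],
            "height": [10.0, 5.0, 5.0, 2.0, 8.0],
            "coverage": [0.5, 0.3, 0.2, 0.4, 0.6],
        }
    )


def random_tree(n_tips: int, seed: int) -> "cs.PhyloTree":
    return cs.simulate_yule(n_tips, seed=seed, depth=1.0)


def brute_force_mntd(sample, dm):
    vals = []
    for a in sample:
        vals.append(min(dm.loc(a, b) for b in sample if b != a))
    return float(np.mean(vals))


def brute_force_mpd(sample, dm):
    vals = []
    for i, a in enumerate(sample):
        for b in sample[i + 1:]:
            vals.append(dm.loc(a, b))
    return float(np.mean(vals))
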