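import numpy as np
import pandas as pd
import pytest

from commphylo import (
    CommunityMatrix,
    TraitTable,
    parse_newick,
    simulate_yule_tree,
)


@pytest.fixture
def small_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def yule20():
    return simulate_yule_tree(20, seed=101)


@pytest.fixture
def yule_pool():
    """Study-sized pool tree used by structure tests."""
    return simulate_yule_tree(164, seed=424242)


@pytest.fixture
def mixed_traits():
    df = pd.DataFrame(
        {
            "mass": [10.0, 20.0, 30.0, 15.0],
            "wing": [5.0, 6.0, 9.0, 5.5],
            "diet_seed": [1.0, 0.0, 0.0, 1.0],
            "diet_insect": [0.0, 1.0, 1.0, 0.0],
        },
        index=["sp1", "sp2", "sp3", "sp4"],
    )
    types = {"mass": "continuous", "wing": "continuous",
             "diet_seed": "binary", "diet_insect": "binary"}
    return TraitTable(df, types)


def random_community(tree, n_sites, richness, rng):
    """Uniform incidence matrix over the tree's tips (test helper)."""
    labels = tree.tip_labels
    inc = np.zeros((n_sites, len(labels)), dtype=int)
    for i in range(n_sites):
        inc[i, rng.choice(len(labels), size=richness, replace=False)] = 1
    return CommunityMatrix(
        pd.DataFrame(inc, index=[f"s{i}" for i in range(n_sites)], columns=labels)
    )
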