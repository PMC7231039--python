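import numpy as np
import pytest

from evotrek.phylo import parse_newick
from evotrek.simulate import simulate_species_tree


@pytest.fixture
def quartet_tree():
    """((A,B),(C,D)) with unit branch lengths."""
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def kch_tree():
    """Two-leaf ingroup plus an outgroup attached at the root."""
    return parse_newick("((A:1,B:1)ST:1,OUT:2);")


def random_tree(n_taxa: int, seed: int):
    return simulate_species_tree(n_taxa, seed, height=1.0)


def random_column(tree, rng: np.random.Generator) -> dict:
    return {name: int(rng.integers(2)) for name in tree.leaf_names()}
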