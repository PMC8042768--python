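import numpy as np
import pytest

from selon.core import (
    PopulationConfig,
    SelectionProfile,
    build_mutation_matrix,
)
from selon.io import UCEAlignment, UCEDataset
from selon.tree import RootedTree


@pytest.fixture
def jc():
    return build_mutation_matrix("JC")


@pytest.fixture
def unrest_unit():
    return build_mutation_matrix("UNREST", np.ones(11))


@pytest.fixture
def pop():
    return PopulationConfig()


@pytest.fixture
def four_taxon_tree():
    return RootedTree.from_newick("((a:0.1,b:0.2):0.05,(c:0.3,d:0.1):0.07);")


@pytest.fixture
def profile():
    return SelectionProfile(nes_max=4.0, center=25.0, width=8.0)


def random_rate_matrix(rng, scale=1.0):
    """A random valid nucleotide rate matrix (nonnegative off-diagonals,
    zero row sums)."""
    q = rng.uniform(0.1, 1.0, size=(4, 4)) * scale
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def random_rooted_tree(rng, n_taxa):
    """Random rooted binary tree over n_taxa leaves with random lengths."""
    labels = [f"t{i}" for i in range(n_taxa)]
    nodes = [f"{lb}:{rng.uniform(0.02, 0.5):.6f}" for lb in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.02, 0.5):.6f}")
    nwk = f"({nodes[0]},{nodes[1]});"
    return RootedTree.from_newick(nwk)


def make_alignment(codes, uce_id="u0", taxa=None):
    codes = np.asarray(codes, dtype=np.int8)
    taxa = taxa or tuple(f"t{i}" for i in range(codes.shape[0]))
    return UCEAlignment(uce_id=uce_id, taxa=tuple(taxa), codes=codes)
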