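import numpy as np
import pytest

from phylodiag.core import Alignment
from phylodiag.simulate import (SimulationConfig, four_cluster_tree,
                                simulate_gene_set)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def tiny_nt_alignment():
    return Alignment(
        ["tax1", "tax2", "tax3", "tax4"],
        ["ACGTAC", "ACGTAC", "ACGTTT", "AC-T?T"],
        "nucleotide",
    )


@pytest.fixture
def tiny_aa_alignment():
    return Alignment(
        ["tax1", "tax2", "tax3"],
        ["MKLV-", "MKLVX", "MKIVA"],
        "amino_acid",
    )


@pytest.fixture(scope="session")
def tiny_gene_set():
    """A small simulated gene set shared across supermatrix tests."""
    tree, groups = four_cluster_tree((2, 2, 2, 2), internal_branch=0.3)
    config = SimulationConfig(tree=tree, n_genes=4, gene_length_range=(40, 60),
                              occupancy=0.85, seed=11)
    genes, _ = simulate_gene_set(config)
    return genes, groups, tree


def random_alignment(rng, n_taxa=5, n_cols=30, alphabet="nucleotide",
                     missing_fraction=0.1):
    from phylodiag.core import states_for

    states = list(states_for(alphabet))
    m = rng.choice(states, size=(n_taxa, n_cols))
    miss = rng.random((n_taxa, n_cols)) < missing_fraction
    m[miss] = "-"
    return Alignment([f"t{i}" for i in range(n_taxa)], m, alphabet)
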