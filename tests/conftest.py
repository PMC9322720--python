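import numpy as np
import pytest

import dtlroot as dr
from dtlroot.rate_policy import RatePolicy
from dtlroot.rooting import root_scan
from dtlroot.simulate import bacteria_like, eukaryote_like, simulate_dataset


@pytest.fixture(scope="session")
def species3():
    return dr.SpeciesTree.from_newick("((A,B),C);")


@pytest.fixture(scope="session")
def species2():
    return dr.SpeciesTree.from_newick("(A,B);")


@pytest.fixture(scope="session")
def bact_small():
    """Small transfer-dominated dataset shared across tests."""
    return simulate_dataset(bacteria_like(n_species=8, n_families=40, seed=11))


@pytest.fixture(scope="session")
def euk_small():
    """Small duplication-rich dataset shared across tests."""
    return simulate_dataset(eukaryote_like(n_species=8, n_families=40, seed=12))


@pytest.fixture(scope="session")
def bact_small_scan(bact_small):
    """Free-policy root scan of the small transfer-dominated dataset."""
    unrooted = bact_small.species_tree.unroot()
    return root_scan(bact_small.gene_trees, unrooted, RatePolicy("free"))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
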