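"""Shared fixtures: small handcrafted datasets and study-shaped simulations."""

import numpy as np
import pytest

from msatpop import GenotypeMatrix, Locus
from msatpop.synthetic import make_study_fixture


@pytest.fixture(scope="session")
def study_fixture():
    """One study-shaped dataset (124 individuals, 9 sites, 8 loci)."""
    return make_study_fixture(seed=11)


@pytest.fixture()
def two_pop_fixed():
    """Two populations fixed for different alleles at every locus."""
    loci = [Locus("A", 2), Locus("B", 2)]
    calls = np.array(
        [[[100, 100], [140, 140]]] * 4 + [[[120, 120], [160, 160]]] * 4
    )
    return GenotypeMatrix(
        [f"p1_{i}" for i in range(4)] + [f"p2_{i}" for i in range(4)],
        ["p1"] * 4 + ["p2"] * 4,
        loci,
        calls,
    )


def make_matrix(pop_alleles, motif=2, n_loci=None):
    """Build a GenotypeMatrix from {pop: list of (a, b) calls per locus}.

    ``pop_alleles`` maps population -> list of individuals, each a list
    of (a, b) pairs (one per locus).
    """
    individuals, populations, rows = [], [], []
    for pop, inds in pop_alleles.items():
        for i, calls in enumerate(inds):
            individuals.append(f"{pop}_{i + 1}")
            populations.append(pop)
            rows.append(calls)
    arr = np.array(rows)
    loci = [Locus(f"L{j + 1}", motif) for j in range(arr.shape[1])]
    return GenotypeMatrix(individuals, populations, loci, arr)
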