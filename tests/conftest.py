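"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest

from mutselpip import (
    CodonAlignment,
    MutationParams,
    PhyloTree,
    build_generator,
    mutsel_bc,
    transition_probabilities,
)
from mutselpip.alignment import MISSING
from mutselpip.codons import UNIVERSAL_CODE


@pytest.fixture
def code():
    return UNIVERSAL_CODE


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def brute_force_site_likelihood(aln: CodonAlignment, tree: PhyloTree,
                                gen, site: int) -> float:
    """Likelihood of one column by exhaustive summation over internal states.

    Independent of the pruning code path: enumerates every joint
    assignment of internal-node states and sums the products of root
    prior and per-edge transition probabilities.
    """
    arrays = tree.flatten()
    P = [transition_probabilities(gen, t) for t in arrays.edge_lengths]
    n_states = gen.Q.shape[0]
    leaf_nodes = set(arrays.leaf_index.values())
    internal = [v for v in range(arrays.n_nodes) if v not in leaf_nodes]
    obs = {}
    for label, v in arrays.leaf_index.items():
        obs[v] = aln.codes[aln.taxa.index(label), site]
    total = 0.0
    for assign in product(range(n_states), repeat=len(internal)):
        state = dict(zip(internal, assign))
        term = gen.pi[state[arrays.root]] if arrays.root in state else None
        if term is None:  # single-leaf tree: root is the leaf itself
            c = obs[arrays.root]
            return 1.0 if c == MISSING else float(gen.pi[c])
        for e, (parent, child, _t) in enumerate(arrays.edges):
            P_e = P[e]
            if child in state:
                term *= P_e[state[parent], state[child]]
            else:
                c = obs[child]
                term *= 1.0 if c == MISSING else P_e[state[parent], c]
        total += term
    return total


@pytest.fixture
def small_mixture():
    """A 3-component profile set, uniform mutation, shared by several tests."""
    return mutsel_bc(0.75), MutationParams.uniform()


def make_alignment(taxa_seqs: dict[str, str]) -> CodonAlignment:
    return CodonAlignment.from_sequences(list(taxa_seqs.items()))
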