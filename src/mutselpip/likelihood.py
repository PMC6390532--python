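"""Phylogenetic likelihoods by pruning, per site and mixture component.

The data at codon site n, D_n, is a column of sense-codon observations
over the leaves of a fixed rooted tree. For each mixture component k,
p(D_n | theta, psi^(k)) is computed by Felsenstein pruning under the
component's mutation-selection generator, with root states weighted by
the component's stationary distribution (the process is assumed at
equilibrium, which reversibility makes consistent with any rooting).
Missing leaves contribute all-ones partials. Partial likelihoods are
rescaled per node so alignments on large trees do not underflow; all
returned values are natural-log likelihoods.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from .alignment import MISSING, CodonAlignment
from .mutation import ComponentGenerator, MutationParams, build_generator, transition_probabilities
from .profiles import ProfileSet
from .trees import PhyloTree, TreeArrays


class LikelihoodError(ValueError):
    """Taxa mismatch between alignment and tree."""


def _component_site_logliks(
    codes: np.ndarray,
    arrays: TreeArrays,
    row_of_node: dict[int, int],
    gen: ComponentGenerator,
    edge_lengths: np.ndarray,
) -> np.ndarray:
    """Log-likelihood of every site under one component generator."""
    n_sites = codes.shape[1]
    n_states = gen.Q.shape[0]
    P = [transition_probabilities(gen, float(t)) for t in edge_lengths]
    partials: dict[int, np.ndarray] = {}
    log_scale = np.zeros(n_sites)
    for v in range(arrays.n_nodes):
        kids = arrays.children[v]
        if not kids:
            part = np.ones((n_sites, n_states))
            obs = codes[row_of_node[v]]
            observed = obs != MISSING
            part[observed] = 0.0
            part[observed, obs[observed]] = 1.0
            partials[v] = part
            continue
        part = np.ones((n_sites, n_states))
        for child, e in kids:
            part *= partials.pop(child) @ P[e].T
        m = part.max(axis=1)
        safe = np.where(m > 0, m, 1.0)
        part /= safe[:, None]
        with np.errstate(divide="ignore"):
            log_scale += np.where(m > 0, np.log(safe), -np.inf)
        partials[v] = part
    root_part = partials[arrays.root]
    L = root_part @ gen.pi
    with np.errstate(divide="ignore"):
        return np.where(L > 0, np.log(np.maximum(L, 1e-300)), -np.inf) + log_scale


class LikelihoodEngine:
    """Caches tree structure and leaf data for repeated N x K table evaluation.

    The allocation samplers only need the table of per-site,
    per-component log-likelihoods; it depends on (rho, phi) and branch
    lengths but not on the allocations themselves, so it is recomputed
    only when those parameters move.
    """

    def __init__(self, aln: CodonAlignment, tree: PhyloTree, profiles: ProfileSet):
        self.aln = aln
        self.tree = tree
        self.profiles = profiles
        self.arrays = tree.flatten()
        tree_taxa = set(self.arrays.leaf_index)
        aln_taxa = set(aln.taxa)
        if tree_taxa != aln_taxa:
            raise LikelihoodError(
                f"alignment/tree taxa mismatch: only in alignment "
                f"{sorted(aln_taxa - tree_taxa)}, only in tree {sorted(tree_taxa - aln_taxa)}"
            )
        self.row_of_node = {
            node: aln.taxa.index(label) for label, node in self.arrays.leaf_index.items()
        }
        self.code = aln.code_table
        self._gen_cache: tuple[bytes, list[ComponentGenerator]] | None = None

    def generators(self, mut: MutationParams) -> list[ComponentGenerator]:
        # cached across calls: branch-length moves reuse the eigensystems
        key = mut.rho.tobytes() + mut.phi.tobytes()
        if self._gen_cache is None or self._gen_cache[0] != key:
            gens = [
                build_generator(mut, p, self.code, component_index=k)
                for k, p in enumerate(self.profiles.components)
            ]
            self._gen_cache = (key, gens)
        return self._gen_cache[1]

    def table(self, mut: MutationParams, edge_lengths: np.ndarray | None = None) -> np.ndarray:
        """N x K matrix of log p(D_n | theta, psi^(k))."""
        if edge_lengths is None:
            edge_lengths = self.arrays.edge_lengths
        cols = [
            _component_site_logliks(self.aln.codes, self.arrays, self.row_of_node, gen, edge_lengths)
            for gen in self.generators(mut)
        ]
        return np.stack(cols, axis=1)


def site_component_likelihood(
    aln: CodonAlignment,
    tree: PhyloTree,
    mut: MutationParams,
    profile_k,
    n: int,
) -> float:
    """Log-likelihood of site ``n`` under a single profile component."""
    pset = ProfileSet((profile_k,))
    engine = LikelihoodEngine(aln, tree, pset)
    if not 0 <= n < aln.n_sites:
        raise IndexError(f"site index {n} out of range")
    return float(engine.table(mut)[n, 0])


def all_site_component_likelihoods(
    aln: CodonAlignment, tree: PhyloTree, mut: MutationParams, profiles: ProfileSet
) -> np.ndarray:
    """N x K table of per-site, per-component log-likelihoods."""
    return LikelihoodEngine(aln, tree, profiles).table(mut)


def mixture_site_likelihood(row_logliks: np.ndarray, weights: np.ndarray) -> float:
    """Log of the weighted-sum mixture likelihood at one site.

    log sum_k w_k p(D_n | theta, psi^(k)), evaluated as a log-sum-exp so
    components spanning hundreds of log units do not underflow.
    """
    w = np.asarray(weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    with np.errstate(divide="ignore"):
        logw = np.where(w > 0, np.log(np.maximum(w, 1e-300)), -np.inf)
    return float(logsumexp(logw + np.asarray(row_logliks, dtype=float)))
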