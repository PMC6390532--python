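"""Simulation of codon alignments under the mixture model.

Each site is assigned a mixture component; the root codon is drawn from
that component's stationary distribution and states are propagated down
the tree by sampling from exp(Q t) along each branch (equivalent in
distribution to event-by-event simulation). A designated monophyletic
sub-clade may use a different component at a chosen set of "shifted"
sites: the new regime applies from the sub-clade's stem branch downward
(the transfer event precedes the sub-clade's most recent common
ancestor). The simulator is the synthetic-data source for the test
suite and the evaluation sweeps (peakedness gradients, branch-length
scaling, precision-recall).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alignment import CodonAlignment
from .codons import UNIVERSAL_CODE
from .mutation import MutationParams, build_generator, transition_probabilities
from .profiles import ProfileSet
from .trees import PhyloTree, TreeError


def draw_allocations(n_sites: int, K: int, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. uniform component allocations for n_sites sites (0-based)."""
    if n_sites < 1 or K < 1:
        raise ValueError("need n_sites >= 1 and K >= 1")
    return rng.integers(K, size=n_sites)


def embed_shifts(
    allocation_main: np.ndarray, n_shift: int, K: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Plant component shifts at n_shift sites chosen uniformly.

    At each selected site the sub-clade allocation is drawn uniformly
    from the K - 1 components different from the main allocation.
    Returns (allocation_sub, truth) where truth holds the 0-based
    indices of the shifted sites.
    """
    allocation_main = np.asarray(allocation_main)
    n_sites = allocation_main.size
    if n_shift > n_sites:
        raise ValueError("cannot shift more sites than exist")
    if n_shift > 0 and K < 2:
        raise ValueError("shifts require at least 2 components")
    truth = np.sort(rng.choice(n_sites, size=n_shift, replace=False))
    allocation_sub = allocation_main.copy()
    for n in truth:
        offset = 1 + int(rng.integers(K - 1))
        allocation_sub[n] = (allocation_main[n] + offset) % K
    return allocation_sub, truth


@dataclass
class SimulationDesign:
    """Complete specification of one simulated alignment.

    ``allocation_sub`` differs from ``allocation_main`` exactly at the
    shifted sites; the sub-clade must be monophyletic in the tree.
    """

    tree: PhyloTree
    subclade: set[str]
    profiles: ProfileSet
    allocation_main: np.ndarray
    allocation_sub: np.ndarray
    mut: MutationParams
    seed: int | None = None

    def __post_init__(self):
        self.allocation_main = np.asarray(self.allocation_main)
        self.allocation_sub = np.asarray(self.allocation_sub)
        if self.allocation_main.shape != self.allocation_sub.shape:
            raise ValueError("allocation vectors must have equal length")
        K = self.profiles.K
        for z in (self.allocation_main, self.allocation_sub):
            if z.size and (z.min() < 0 or z.max() >= K):
                raise ValueError("allocation index out of range")
        if self.subclade and not self.tree.is_monophyletic(self.subclade):
            raise TreeError("sub-clade is not monophyletic")

    @property
    def n_sites(self) -> int:
        return self.allocation_main.size

    @property
    def truth(self) -> np.ndarray:
        """0-based indices of sites simulated with a shifted component."""
        return np.flatnonzero(self.allocation_main != self.allocation_sub)

    @property
    def n_shift(self) -> int:
        return int(self.truth.size)

    def to_json(self, path: str | Path) -> None:
        record = {
            "seed": self.seed,
            "n_sites": int(self.n_sites),
            "n_shift": self.n_shift,
            "K": self.profiles.K,
            "peakedness": self.profiles.peakedness,
            "profile_source": self.profiles.source,
            "subclade": sorted(self.subclade),
            "n_taxa": self.tree.n_leaves,
            "total_tree_length": self.tree.total_length,
            "rho": [float(x) for x in self.mut.rho],
            "phi": [float(x) for x in self.mut.phi],
            "allocation_main": [int(x) for x in self.allocation_main],
            "allocation_sub": [int(x) for x in self.allocation_sub],
        }
        with open(path, "w") as fh:
            json.dump(record, fh, indent=2)
            fh.write("\n")

    def write_truth_tsv(self, path: str | Path) -> None:
        """Site-level truth table (1-based sites; components 1-based)."""
        truth = set(self.truth.tolist())
        with open(path, "w") as fh:
            fh.write("site\tmain_component\tsub_component\tshifted\n")
            for n in range(self.n_sites):
                fh.write(
                    f"{n + 1}\t{self.allocation_main[n] + 1}\t"
                    f"{self.allocation_sub[n] + 1}\t{int(n in truth)}\n"
                )


def _subclade_edge_mask(tree: PhyloTree, subclade: set[str]) -> np.ndarray:
    """Edge mask (flatten() order): True on the stem and inside the sub-clade."""
    arrays = tree.flatten()
    if not subclade:
        return np.zeros(len(arrays.edges), dtype=bool)
    nodes = list(tree.dendropy_tree.postorder_node_iter())
    mrca = tree.dendropy_tree.mrca(taxon_labels=list(subclade))
    inside_ids = {id(n) for n in mrca.preorder_iter()}
    inside = np.array([id(n) in inside_ids for n in nodes])
    return np.array([inside[child] for (_, child, _) in arrays.edges])


def _categorical_rows(P_rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One draw per row from row-wise categorical distributions."""
    cum = np.cumsum(P_rows, axis=1)
    u = rng.random(P_rows.shape[0]) * cum[:, -1]
    idx = (u[:, None] >= cum).sum(axis=1)
    return np.minimum(idx, P_rows.shape[1] - 1)


def simulate_alignment(
    design: SimulationDesign, rng: np.random.Generator | int | None = None
) -> tuple[CodonAlignment, np.ndarray]:
    """Simulate a codon alignment under the design.

    Returns the alignment (taxa in tree leaf order) and the 0-based
    truth indices of shifted sites.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    tree = design.tree
    arrays = tree.flatten()
    code = UNIVERSAL_CODE
    n_sites = design.n_sites
    n_states = code.n_codons

    used = set(design.allocation_main.tolist()) | set(design.allocation_sub.tolist())
    gens = {
        k: build_generator(design.mut, design.profiles[k], code, component_index=k)
        for k in used
    }
    sub_mask = _subclade_edge_mask(tree, design.subclade)

    # per-edge component assignment per site
    comp_main = design.allocation_main
    comp_sub = design.allocation_sub

    states = np.empty((arrays.n_nodes, n_sites), dtype=np.int64)
    root_states = np.empty(n_sites, dtype=np.int64)
    for k in used:
        sites = np.flatnonzero(comp_main == k)
        if sites.size:
            root_states[sites] = rng.choice(n_states, size=sites.size, p=gens[k].pi)
    states[arrays.root] = root_states

    # cache transition matrices per (component, edge length)
    P_cache: dict[tuple[int, float], np.ndarray] = {}

    def P_of(k: int, t: float) -> np.ndarray:
        key = (k, t)
        if key not in P_cache:
            P_cache[key] = transition_probabilities(gens[k], t)
        return P_cache[key]

    # edges into a node appear later in the list than edges out of it,
    # so reversed order visits every parent before its children
    for e in reversed(range(len(arrays.edges))):
        parent, child, length = arrays.edges[e]
        comps = comp_sub if sub_mask[e] else comp_main
        child_states = np.empty(n_sites, dtype=np.int64)
        for k in used:
            sites = np.flatnonzero(comps == k)
            if not sites.size:
                continue
            P = P_of(k, float(length))
            child_states[sites] = _categorical_rows(P[states[parent, sites]], rng)
        states[child] = child_states

    # leaves in tree order
    taxa = tree.leaf_labels
    rows = np.stack([states[arrays.leaf_index[t]] for t in taxa])
    aln = CodonAlignment(taxa=taxa, codes=rows, code_table=code)
    return aln, design.truth


def make_design(
    n_taxa: int,
    clade_size: int,
    n_sites: int,
    n_shift: int,
    profiles: ProfileSet,
    rng: np.random.Generator | int,
    mean_branch: float = 0.3,
    mut: MutationParams | None = None,
    tree: PhyloTree | None = None,
    subclade: set[str] | None = None,
) -> SimulationDesign:
    """Convenience constructor: random tree + allocations + planted shifts."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    from .trees import random_tree

    if tree is None or subclade is None:
        tree, subclade = random_tree(n_taxa, mean_branch, rng, clade_size=clade_size)
    z_main = draw_allocations(n_sites, profiles.K, rng)
    z_sub, _ = embed_shifts(z_main, n_shift, profiles.K, rng)
    return SimulationDesign(
        tree=tree,
        subclade=subclade,
        profiles=profiles,
        allocation_main=z_main,
        allocation_sub=z_sub,
        mut=mut or MutationParams.uniform(),
    )
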