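"""Rooted phylogenies with branch lengths, and sub-clade partition surgery.

Trees are held as dendropy objects behind a thin wrapper that fixes the
conventions the model needs: rooted, leaf labels unique and matching
alignment taxa, branch lengths in expected substitutions per codon site
(under the unit-rate generator normalization). The focal sub-clade
partition drops the stem branch connecting the sub-clade to the rest of
the tree — the two partitions are analyzed as fully independent, i.e.
as if that branch were of infinite length.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np


class TreeError(ValueError):
    """Invalid tree, taxa mismatch, or non-monophyletic sub-clade."""


@dataclass
class TreeArrays:
    """Flattened postorder view of a tree for likelihood computation.

    nodes are indexed 0..n_nodes-1 in postorder (root last); ``edges``
    lists (parent, child, length) with children appearing before their
    parent; ``children[v]`` gives (child_index, edge_index) pairs;
    ``leaf_index`` maps leaf label -> node index.
    """

    n_nodes: int
    root: int
    children: list[list[tuple[int, int]]]
    edges: list[tuple[int, int, float]]
    leaf_index: dict[str, int]

    @property
    def edge_lengths(self) -> np.ndarray:
        return np.array([e[2] for e in self.edges])


class PhyloTree:
    """A rooted tree with branch lengths (dendropy-backed)."""

    def __init__(self, tree: dendropy.Tree):
        tree.is_rooted = True
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise TreeError("duplicate leaf labels")
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            if node.edge.length is None:
                raise TreeError("tree has branches without lengths")
            if node.edge.length < 0:
                raise TreeError("negative branch length")

    # -- construction -------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree)

    @classmethod
    def read(cls, path: str | Path) -> "PhyloTree":
        tree = dendropy.Tree.get(path=str(path), schema="newick")
        return cls(tree)

    # -- basic accessors ----------------------------------------------
    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def total_length(self) -> float:
        return sum(
            node.edge.length
            for node in self._tree.preorder_node_iter()
            if node is not self._tree.seed_node and node.edge.length is not None
        )

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # -- flattening ----------------------------------------------------
    def flatten(self) -> TreeArrays:
        nodes = list(self._tree.postorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        children: list[list[tuple[int, int]]] = [[] for _ in nodes]
        edges: list[tuple[int, int, float]] = []
        leaf_index: dict[str, int] = {}
        for i, node in enumerate(nodes):
            if node.is_leaf():
                leaf_index[node.taxon.label] = i
            for child in node.child_nodes():
                e = len(edges)
                edges.append((i, index[id(child)], float(child.edge.length)))
                children[i].append((index[id(child)], e))
        return TreeArrays(
            n_nodes=len(nodes),
            root=index[id(self._tree.seed_node)],
            children=children,
            edges=edges,
            leaf_index=leaf_index,
        )

    def set_edge_lengths(self, lengths: np.ndarray) -> "PhyloTree":
        """Return a copy with branch lengths replaced, in flatten() edge order."""
        new = self.copy()
        nodes = list(new._tree.postorder_node_iter())
        k = 0
        for node in nodes:
            for child in node.child_nodes():
                child.edge.length = float(lengths[k])
                k += 1
        return new

    # -- sub-clade handling ---------------------------------------------
    def _mrca(self, taxa: set[str]) -> dendropy.Node:
        unknown = taxa - set(self.leaf_labels)
        if unknown:
            raise TreeError(f"taxa not in tree: {sorted(unknown)}")
        return self._tree.mrca(taxon_labels=list(taxa))

    def is_monophyletic(self, taxa: set[str]) -> bool:
        mrca = self._mrca(set(taxa))
        under = {leaf.taxon.label for leaf in mrca.leaf_iter()}
        return under == set(taxa)

    def extract_subclade(self, taxa: set[str]) -> "PhyloTree":
        """Induced subtree of a monophyletic taxon set, stem branch dropped."""
        taxa = set(taxa)
        if not self.is_monophyletic(taxa):
            raise TreeError("sub-clade is not monophyletic")
        if len(taxa) < 2:
            raise TreeError("sub-clade must contain at least 2 taxa")
        sub = self._tree.extract_tree_with_taxa_labels(taxa)
        sub.seed_node.edge.length = None  # the stem is severed
        return PhyloTree(sub)

    def remove_taxa(self, taxa: set[str]) -> "PhyloTree":
        """Complement partition: drop the given taxa, suppressing unifurcations."""
        keep = set(self.leaf_labels) - set(taxa)
        if len(keep) < 2:
            raise TreeError("remaining partition must contain at least 2 taxa")
        rest = self._tree.extract_tree_with_taxa_labels(keep)
        rest.seed_node.edge.length = None
        return PhyloTree(rest)


def read_tree(path: str | Path) -> PhyloTree:
    """Read a rooted Newick tree with branch lengths."""
    return PhyloTree.read(path)


def read_taxon_set(path: str | Path) -> set[str]:
    """Read a sub-clade taxon list, one label per line ('#' comments allowed)."""
    taxa = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                taxa.add(line)
    if not taxa:
        raise TreeError("empty taxon set")
    return taxa


def scale_branches(tree: PhyloTree, factor: float) -> PhyloTree:
    """Multiply every branch length by ``factor`` (> 0); topology unchanged."""
    if factor <= 0:
        raise ValueError(f"scale factor must be positive, got {factor}")
    new = tree.copy()
    for node in new.dendropy_tree.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length *= factor
    return new


def split_by_subclade(
    aln, tree: PhyloTree, subclade: set[str]
) -> tuple[tuple["object", PhyloTree], tuple["object", PhyloTree]]:
    """Partition an alignment and tree into (sub-clade, remainder) pairs.

    The sub-clade must be monophyletic. Each partition keeps its induced
    subtree with the connecting stem branch removed; site indexing is
    preserved in both alignments.
    """
    subclade = set(subclade)
    sub_tree = tree.extract_subclade(subclade)
    rest_tree = tree.remove_taxa(subclade)
    sub_aln = aln.subset(sorted(subclade, key=aln.taxa.index))
    rest_taxa = [t for t in aln.taxa if t not in subclade]
    rest_aln = aln.subset(rest_taxa)
    return (sub_aln, sub_tree), (rest_aln, rest_tree)


def random_tree(
    n_taxa: int,
    mean_branch: float,
    rng: np.random.Generator,
    clade_size: int | None = None,
) -> tuple[PhyloTree, set[str]]:
    """Random rooted binary tree with exponential branch lengths.

    Topology is built by uniform random coalescent-style joins. If
    ``clade_size`` is given, taxa t1..t{clade_size} are constrained to
    form a monophyletic clade (they coalesce among themselves first),
    providing the focal group for shift experiments.

    Returns the tree and the clade taxon set (empty if no clade asked).
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if clade_size is not None and not 2 <= clade_size < n_taxa:
        raise ValueError("clade size must be in [2, n_taxa)")
    labels = [f"t{i+1}" for i in range(n_taxa)]
    taxon_ns = dendropy.TaxonNamespace(labels)

    def make_leaf(label: str) -> dendropy.Node:
        node = dendropy.Node()
        node.taxon = taxon_ns.get_taxon(label)
        return node

    def join(pool: list[dendropy.Node]) -> None:
        i, j = rng.choice(len(pool), size=2, replace=False)
        a, b = pool[int(i)], pool[int(j)]
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = float(rng.exponential(mean_branch))
        b.edge.length = float(rng.exponential(mean_branch))
        pool[:] = [n for n in pool if n is not a and n is not b] + [parent]

    clade_labels = set(labels[:clade_size]) if clade_size else set()
    clade_pool = [make_leaf(l) for l in labels[:clade_size]] if clade_size else []
    rest_pool = [make_leaf(l) for l in labels[clade_size or 0:]]
    while len(clade_pool) > 1:
        join(clade_pool)
    pool = rest_pool + clade_pool
    while len(pool) > 1:
        join(pool)
    tree = dendropy.Tree(taxon_namespace=taxon_ns, seed_node=pool[0])
    return PhyloTree(tree), clade_labels
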