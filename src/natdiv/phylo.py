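"""Phylogeny handling: Newick I/O, pruning, and the phylogenetic covariance.

The tree is a rooted, time-calibrated family-level phylogeny with branch
lengths in Myr.  Two quantities derived from it drive the analysis:

* per-tip **stem ages** (time from a tip's parent node to the present),
  the ``t`` of the method-of-moments diversification estimator; and
* the **phylogenetic correlation matrix** ``A`` whose entry (i, j) is the
  shared root-to-MRCA path length of tips i and j, rescaled to unit
  diagonal.  ``A`` is the random-effect covariance structure of the
  phylogenetic mixed model.

Parsing, serialization and topology surgery delegate to :mod:`dendropy`;
the covariance construction and stem-age logic live here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "NewickError",
    "read_newick",
    "write_newick",
    "prune",
    "phylo_covariance",
]


class NewickError(ValueError):
    """Raised for malformed Newick input or missing branch lengths."""


@dataclass
class PhyloCovariance:
    """Phylogenetic correlation matrix in a fixed tip order.

    ``matrix`` is symmetric positive semidefinite with unit diagonal;
    off-diagonal entries are shared-history fractions in [0, 1].
    """

    labels: list[str]
    matrix: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


class Phylogeny:
    """Rooted tree with branch lengths in Myr, tips labelled by family.

    Wraps a :class:`dendropy.Tree`; all mutating operations return new
    objects.  Node ages are measured from the deepest tip (the present for
    an ultrametric tree); non-ultrametric trees are accepted.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()

    # -- construction ------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise NewickError(f"malformed Newick: {exc}") from exc
        return cls(tree)

    def _validate(self) -> None:
        labels = []
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise NewickError("unlabelled tip in tree")
            labels.append(leaf.taxon.label)
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise NewickError(f"duplicate tip labels: {dupes}")
        if not labels:
            raise NewickError("tree has no tips")
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            bl = node.edge.length
            if bl is None:
                raise NewickError(
                    f"missing branch length on edge above "
                    f"{node.taxon.label if node.taxon else 'internal node'}"
                )
            if not np.isfinite(bl) or bl < 0:
                raise NewickError(f"invalid branch length {bl!r}")

    # -- basic queries -----------------------------------------------

    @property
    def tips(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self._tree.leaf_nodes())

    def _root_distances(self) -> dict:
        dist = {self._tree.seed_node: 0.0}
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            dist[node] = dist[node.parent_node] + node.edge.length
        return dist

    def depth(self) -> float:
        """Maximum root-to-tip path length (Myr)."""
        dist = self._root_distances()
        return max(dist[leaf] for leaf in self._tree.leaf_node_iter())

    def tip_depths(self) -> dict[str, float]:
        dist = self._root_distances()
        return {leaf.taxon.label: dist[leaf] for leaf in self._tree.leaf_node_iter()}

    def stem_age(self, tip: str) -> float:
        """Age (Myr before present) of the tip's parent node.

        The present is the deepest tip of the tree; for an ultrametric tree
        this is the usual divergence-from-sister time.
        """
        ages = self.stem_ages()
        if tip not in ages:
            raise KeyError(f"unknown tip {tip!r}")
        return ages[tip]

    def stem_ages(self) -> dict[str, float]:
        dist = self._root_distances()
        depth = max(dist[leaf] for leaf in self._tree.leaf_node_iter())
        out = {}
        for leaf in self._tree.leaf_node_iter():
            parent = leaf.parent_node
            parent_dist = dist[parent] if parent is not None else 0.0
            out[leaf.taxon.label] = depth - parent_dist
        return out

    def path_length(self, a: str, b: str) -> float:
        """Patristic distance between two tips."""
        pdm = self._tree.phylogenetic_distance_matrix()
        ta = self._tree.taxon_namespace.get_taxon(a)
        tb = self._tree.taxon_namespace.get_taxon(b)
        if ta is None or tb is None:
            missing = [l for l, t in ((a, ta), (b, tb)) if t is None]
            raise KeyError(f"unknown tips: {missing}")
        return pdm.patristic_distance(ta, tb)

    # -- surgery -----------------------------------------------------

    def prune(self, keep) -> "Phylogeny":
        keep = set(keep)
        tipset = set(self.tips)
        missing = sorted(keep - tipset)
        if missing:
            raise KeyError(f"labels not in tree: {missing}")
        if len(keep) < 2:
            raise ValueError("pruning requires >= 2 retained tips")
        clone = self._tree.clone(depth=1)
        taxa = [t for t in clone.taxon_namespace if t.label in keep]
        clone.retain_taxa(taxa)
        # collapse degree-2 nodes, summing branch lengths
        clone.suppress_unifurcations()
        return Phylogeny(clone)

    # -- serialization -----------------------------------------------

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        )
        return s.strip() + ("\n" if not s.endswith("\n") else "")

    # -- covariance --------------------------------------------------

    def covariance(self, order=None) -> PhyloCovariance:
        """Shared-path-length matrix rescaled to correlation form.

        ``matrix[i, j]`` is the root-to-MRCA path length of tips i and j,
        divided by ``sqrt(depth_i * depth_j)`` so the diagonal is 1.
        """
        labels = list(order) if order is not None else self.tips
        tipset = set(self.tips)
        missing = sorted(set(labels) - tipset)
        if missing:
            raise KeyError(f"labels not in tree: {missing}")
        if len(labels) < 2:
            raise ValueError("covariance requires >= 2 tips")

        idx = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        dist = self._root_distances()
        cov = np.zeros((n, n))

        # postorder sweep: MRCA depth of any cross-child tip pair at a node
        # is that node's root distance
        tips_below: dict = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                lab = node.taxon.label
                tips_below[node] = [idx[lab]] if lab in idx else []
                continue
            child_sets = [tips_below.pop(c) for c in node.child_nodes()]
            d = dist[node]
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    for i in child_sets[a]:
                        for j in child_sets[b]:
                            cov[i, j] = cov[j, i] = d
            merged = [i for s in child_sets for i in s]
            tips_below[node] = merged

        depths = np.array([dist[leaf] for leaf in self._tree.leaf_node_iter()
                           if leaf.taxon.label in idx])
        leaf_labels = [leaf.taxon.label for leaf in self._tree.leaf_node_iter()
                       if leaf.taxon.label in idx]
        d = np.empty(n)
        for lab, dep in zip(leaf_labels, depths):
            d[idx[lab]] = dep
        if np.any(d <= 0):
            bad = [labels[i] for i in np.where(d <= 0)[0]]
            raise ValueError(f"zero root-to-tip depth for tips {bad}; cannot rescale")
        np.fill_diagonal(cov, d)
        scale = 1.0 / np.sqrt(d)
        corr = cov * scale[:, None] * scale[None, :]
        corr = (corr + corr.T) / 2.0
        return PhyloCovariance(labels=labels, matrix=corr)


# -- module-level functional surface ----------------------------------


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string (branch lengths mandatory) into a Phylogeny."""
    return Phylogeny.from_newick(text)


def write_newick(tree: Phylogeny) -> str:
    return tree.to_newick()


def prune(tree: Phylogeny, keep) -> Phylogeny:
    """Restrict the tree to ``keep``, preserving pairwise tip path lengths."""
    return tree.prune(keep)


def phylo_covariance(tree: Phylogeny, order=None) -> PhyloCovariance:
    """Phylogenetic correlation matrix of the tree in the given tip order."""
    return tree.covariance(order)
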