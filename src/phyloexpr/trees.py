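"""Rooted ultrametric phylogenies and the matrix algebra built on them.

The tree is the backbone of every phylogeny-aware step in the pipeline:
the Brownian-motion covariance feeds generalized least squares, and the
patristic distance matrix feeds PCoA and distance-conditioned missingness.
"""

from __future__ import annotations

import io as _io
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = ["Phylogeny", "bm_covariance", "patristic_distances"]


class PhylogenyError(ValueError):
    pass


class Phylogeny:
    """A rooted tree with unique tip labels and non-negative branch lengths.

    Branch lengths are in million years throughout the pipeline. Thin wrapper
    over a :class:`dendropy.Tree`; all pipeline code goes through this class
    so that validation happens exactly once, at construction.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, source: str) -> "Phylogeny":
        """Parse a Newick string (not a path; see :func:`read_newick`)."""
        try:
            tree = dendropy.Tree.get(
                data=source, schema="newick", preserve_underscores=True
            )
        except dendropy.utility.error.DataParseError as exc:
            if "duplicate" in str(exc).lower():
                raise PhylogenyError(f"duplicate tip labels: {exc}") from None
            raise PhylogenyError(str(exc)) from None
        return cls(tree)

    def _validate(self) -> None:
        labels = []
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise PhylogenyError("tree contains an unlabeled tip")
            labels.append(leaf.taxon.label)
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise PhylogenyError(f"duplicate tip labels: {dupes}")
        for edge in self._tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise PhylogenyError(f"negative branch length {edge.length}")
        self._labels = labels

    # -- basic queries -----------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return list(self._labels)

    @property
    def n_tips(self) -> int:
        return len(self._labels)

    def to_newick(self) -> str:
        s = self._tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def depths(self) -> dict[str, float]:
        """Root-to-tip path lengths keyed by tip label.

        Includes the root's own stem edge when one is set, so that pruning
        (which records the trimmed root path as a stem) preserves depths.
        """
        stem = self._tree.seed_node.edge.length or 0.0
        out = {}
        for leaf in self._tree.leaf_node_iter():
            d = stem
            node = leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            out[leaf.taxon.label] = d
        return out

    def depth(self) -> float:
        return max(self.depths().values())

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = np.array(list(self.depths().values()))
        span = d.max() - d.min()
        return bool(span <= rel_tol * max(d.max(), 1.0))

    # -- algebra -----------------------------------------------------------

    def prune(self, taxa: Iterable[str]) -> "Phylogeny":
        """Restrict to a taxon subset, preserving path lengths between kept tips."""
        keep = list(dict.fromkeys(taxa))
        missing = set(keep) - set(self._labels)
        if missing:
            raise PhylogenyError(f"taxa not in tree: {sorted(missing)}")
        if not keep:
            raise PhylogenyError("empty taxon set")
        old_depth = self.depths()[keep[0]]
        tree = self._tree.clone(depth=1)
        tree.retain_taxa_with_labels(keep)
        pruned = Phylogeny(tree)
        # record any root path trimmed away by pruning as a stem edge, so
        # prune-then-covariance equals covariance-then-subselect
        delta = old_depth - pruned.depths()[keep[0]]
        if delta > 0:
            stem = tree.seed_node.edge.length or 0.0
            tree.seed_node.edge.length = stem + delta
        return Phylogeny(tree)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny(n_tips={self.n_tips}, depth={self.depth():.3g})"


def read_newick(path) -> Phylogeny:
    """Read a Newick file into a validated :class:`Phylogeny`."""
    with open(path) as fh:
        return Phylogeny.from_newick(fh.read())


def _mrca_depth_matrix(phy: Phylogeny, taxa: Sequence[str]) -> np.ndarray:
    """C[i, j] = shared root-to-MRCA path length for the given taxa."""
    tree = phy._tree
    taxa = list(taxa)
    n = len(taxa)
    # root-to-node depth for every node
    depth_of = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depth_of[node] = tree.seed_node.edge.length or 0.0
        else:
            depth_of[node] = depth_of[node.parent_node] + (node.edge.length or 0.0)
    leaf_by_label = {
        leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()
    }
    # ancestor chains (node id path from root) per tip
    paths = {}
    for t in taxa:
        node = leaf_by_label[t]
        chain = []
        while node is not None:
            chain.append(node)
            node = node.parent_node
        paths[t] = list(reversed(chain))
    C = np.zeros((n, n))
    for i in range(n):
        pi = paths[taxa[i]]
        C[i, i] = depth_of[pi[-1]]
        for j in range(i + 1, n):
            pj = paths[taxa[j]]
            mrca = None
            for a, b in zip(pi, pj):
                if a is b:
                    mrca = a
                else:
                    break
            C[i, j] = C[j, i] = depth_of[mrca]
    return C


def bm_covariance(phy: Phylogeny, taxa: Sequence[str] | None = None) -> np.ndarray:
    """Brownian-motion covariance: shared root-to-MRCA path lengths.

    C[i, j] is the path length from the root to the MRCA of tips i and j;
    the diagonal holds root-to-tip depths. Computed on the full tree so that
    restricting to a taxon subset yields exactly the corresponding sub-block
    (equivalently: pruning preserves retained path lengths).
    """
    if taxa is None:
        taxa = phy.tip_labels
    taxa = list(taxa)
    if not taxa:
        raise PhylogenyError("empty taxa set")
    missing = set(taxa) - set(phy.tip_labels)
    if missing:
        raise PhylogenyError(f"taxa not in tree: {sorted(missing)}")
    return _mrca_depth_matrix(phy, taxa)


def patristic_distances(
    phy: Phylogeny, taxa: Sequence[str] | None = None
) -> np.ndarray:
    """Pairwise path-length (patristic) distance matrix, zero diagonal."""
    if taxa is None:
        taxa = phy.tip_labels
    taxa = list(taxa)
    C = _mrca_depth_matrix(phy, taxa)
    depths = np.diag(C)
    return depths[:, None] + depths[None, :] - 2.0 * C
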