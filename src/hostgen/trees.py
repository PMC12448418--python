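"""Rooted, branch-length-bearing phylogenies (host or bacterial).

Thin wrapper over a dendropy tree that validates branch lengths up front
and precomputes a tip-by-edge incidence structure so that Faith's PD and
patristic distances are cheap vectorized operations.  Trees without
branch lengths are rejected: every downstream quantity (PD, SES-PD,
patristic and nearest-neighbor distances) is meaningless without them.
"""

from __future__ import annotations

import io
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd


class TreeError(ValueError):
    """Raised for malformed or unusable trees."""


class PhyloTree:
    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(tips)) != len(tips):
            raise TreeError("duplicate tip labels")
        if len(tips) < 2:
            raise TreeError("tree must have at least 2 tips")
        self.tips: tuple = tuple(tips)
        self._tip_index = {t: i for i, t in enumerate(tips)}

        # collect every edge with a parent; the root's own edge (if any)
        # carries no information about tip relationships beyond an offset
        # and is included only when it has an explicit length.
        edges = []
        lengths = []
        node_edge: dict = {}
        root = tree.seed_node
        for node in tree.preorder_node_iter():
            if node is root:
                continue
            if node.edge.length is None:
                raise TreeError("tree has an edge without a branch length")
            if node.edge.length < 0:
                raise TreeError("negative branch length")
            node_edge[node] = len(edges)
            edges.append(node)
            lengths.append(float(node.edge.length))
        self.edge_lengths = np.asarray(lengths, dtype=float)
        n_tips, n_edges = len(tips), len(edges)
        incidence = np.zeros((n_tips, n_edges), dtype=bool)
        for leaf in tree.leaf_node_iter():
            i = self._tip_index[leaf.taxon.label]
            node = leaf
            while node is not root:
                incidence[i, node_edge[node]] = True
                node = node.parent_node
        self._incidence = incidence
        self._patristic: pd.DataFrame | None = None

    # -- construction ----------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises several error types
            raise TreeError(f"unparseable Newick: {exc}") from exc
        return cls(tree)

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def total_length(self) -> float:
        """Sum of all branch lengths."""
        return float(self.edge_lengths.sum())

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    # -- PD --------------------------------------------------------------
    def _tip_rows(self, tip_labels: Iterable[str]) -> np.ndarray:
        rows = []
        for t in tip_labels:
            if t not in self._tip_index:
                raise TreeError(f"unknown tip: {t!r}")
            rows.append(self._tip_index[t])
        if not rows:
            raise TreeError("empty tip set")
        return np.asarray(rows, dtype=np.intp)

    def faith_pd(self, tip_labels: Iterable[str]) -> float:
        """Faith's phylogenetic diversity of a tip set, root included.

        Total branch length of the minimal subtree connecting the tips to
        the root: the union of each tip's root path.  A single tip yields
        its root-path length.
        """
        rows = self._tip_rows(tip_labels)
        mask = self._incidence[rows].any(axis=0)
        return float(self.edge_lengths[mask].sum())

    def faith_pd_sets(self, sets: np.ndarray) -> np.ndarray:
        """Vectorized PD for many tip sets.

        ``sets`` is a boolean array of shape (n_sets, n_tips) in the order
        of ``self.tips``.  Rows must be non-empty.
        """
        sets = np.asarray(sets, dtype=bool)
        union = sets @ self._incidence.astype(np.float64)  # counts per edge
        return (union > 0) @ self.edge_lengths

    def tip_set_matrix(self, tip_label_sets: Sequence[Iterable[str]]) -> np.ndarray:
        out = np.zeros((len(tip_label_sets), self.n_tips), dtype=bool)
        for k, labels in enumerate(tip_label_sets):
            out[k, self._tip_rows(labels)] = True
        return out

    # -- distances -------------------------------------------------------
    def patristic_matrix(self) -> pd.DataFrame:
        """All-pairs branch-length path distances between tips."""
        if self._patristic is None:
            weighted = self._incidence * self.edge_lengths  # tips x edges
            shared = weighted @ self._incidence.T  # depth of the MRCA
            depth = np.diag(shared)
            dist = depth[:, None] + depth[None, :] - 2.0 * shared
            np.fill_diagonal(dist, 0.0)
            self._patristic = pd.DataFrame(
                dist, index=list(self.tips), columns=list(self.tips)
            )
        return self._patristic

    def patristic_distance(self, a: str, b: str) -> float:
        if a not in self._tip_index or b not in self._tip_index:
            raise TreeError("tip not in tree")
        if a == b:
            return 0.0
        return float(self.patristic_matrix().loc[a, b])

    def nearest_neighbor_distances(self) -> pd.Series:
        """Per-tip minimum patristic distance to any other tip."""
        d = self.patristic_matrix().to_numpy().copy()
        np.fill_diagonal(d, np.inf)
        return pd.Series(d.min(axis=1), index=list(self.tips))

    # -- clades ----------------------------------------------------------
    def clades(self, min_size: int = 2, max_frac: float = 1.0) -> list:
        """Tip-label sets of internal nodes with >= min_size tips.

        ``max_frac`` caps the clade size as a fraction of all tips, so a
        caller can ask for proper subclades only.
        """
        out = []
        cap = max_frac * self.n_tips
        for node in self._tree.preorder_internal_node_iter():
            labels = frozenset(l.taxon.label for l in node.leaf_iter())
            if min_size <= len(labels) <= cap:
                out.append(labels)
        return out


def read_tree(path) -> PhyloTree:
    """Read a rooted Newick tree with branch lengths from ``path``."""
    with open(path) as fh:
        return PhyloTree.from_newick(fh.read())


def write_tree(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
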