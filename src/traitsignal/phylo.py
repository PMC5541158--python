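"""Phylogeny handling: newick I/O, midpoint rooting, tree-trait joins, VCV.

Trees are held as rooted :class:`dendropy.Tree` objects wrapped in a thin
:class:`Phylogeny` that enforces the invariants the signal statistics rely
on (unique tip labels, nonnegative branch lengths, a single root).  The
phylogenetic variance-covariance matrix is computed here: under Brownian
motion the covariance of two tips equals the branch length shared on their
root-to-tip paths, i.e. the depth of their most recent common ancestor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "TipTraitMap",
    "parse_newick",
    "midpoint_root",
    "prune_join",
    "vcv_matrix",
    "tip_distance_matrix",
]


class NewickParseError(ValueError):
    """Malformed newick input (dendropy's diagnostic, including position)."""


class Phylogeny:
    """A rooted phylogenetic tree with branch lengths and unique tip labels.

    Polytomies are allowed.  Branch lengths missing from the input are set
    to 1.0 with a warning (the root edge is exempt: its length is
    meaningless for a rooted tree).
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error classes
            raise NewickParseError(str(exc)) from exc
        return cls(tree)

    def _validate(self) -> None:
        labels = []
        missing_bl = 0
        for node in self._tree.preorder_node_iter():
            if node.parent_node is not None:
                if node.edge.length is None:
                    node.edge.length = 1.0
                    missing_bl += 1
                elif node.edge.length < 0:
                    raise ValueError(
                        f"negative branch length {node.edge.length!r}"
                    )
            if node.is_leaf():
                label = node.taxon.label if node.taxon else None
                if label is None:
                    raise ValueError("unlabeled tip in tree")
                labels.append(label)
        if missing_bl:
            warnings.warn(
                f"{missing_bl} branch length(s) missing; defaulted to 1.0",
                stacklevel=3,
            )
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise ValueError(f"duplicate tip labels: {sorted(dupes)}")
        self._tip_labels = sorted(labels)

    # -- basic queries ------------------------------------------------

    @property
    def tree(self) -> dendropy.Tree:
        """The underlying dendropy tree (treat as read-only)."""
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        """Tip labels in sorted order (the canonical matrix order)."""
        return list(self._tip_labels)

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    def copy(self) -> "Phylogeny":
        return Phylogeny(self._tree.clone(depth=1))

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True
        ).strip()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Phylogeny(n_tips={self.n_tips})"


@dataclass
class TipTraitMap:
    """Trait values keyed by tip label.

    ``kind`` is ``"continuous"`` or ``"binary"``; binary values must be
    exactly 0/1.
    """

    values: dict[str, float]
    name: str = "trait"
    kind: str = "continuous"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown trait kind {self.kind!r}")
        if self.kind == "binary":
            bad = {v for v in self.values.values() if v not in (0, 1)}
            if bad:
                raise ValueError(f"binary trait has non-0/1 values: {bad}")

    def vector(self, labels: list[str]) -> np.ndarray:
        """Values aligned to ``labels`` (raises on a missing tip)."""
        return np.array([float(self.values[l]) for l in labels])

    def __len__(self) -> int:
        return len(self.values)


def parse_newick(source) -> Phylogeny:
    """Read a newick tree from a path or a literal newick string."""
    import os

    if isinstance(source, (str, os.PathLike)) and os.path.exists(source):
        with open(source) as fh:
            text = fh.read()
    else:
        text = str(source)
    return Phylogeny.from_newick(text)


def midpoint_root(t: Phylogeny) -> Phylogeny:
    """Reroot at the midpoint of the longest tip-to-tip path.

    Tip-to-tip distances are invariant under rerooting, so the output's
    distance matrix equals the input's.  All-zero branch lengths leave the
    midpoint undefined and raise.
    """
    if t.n_tips < 2:
        raise ValueError("midpoint rooting needs at least 2 tips")
    total = sum(
        node.edge.length
        for node in t.tree.preorder_node_iter()
        if node.parent_node is not None
    )
    if total <= 0:
        raise ValueError("all branch lengths are zero; midpoint undefined")
    # rebuild from newick: dendropy's midpoint routine requires freshly
    # encoded bipartitions, and clones can carry stale encoding state
    clone = dendropy.Tree.get(
        data=t.to_newick(), schema="newick", preserve_underscores=True
    )
    clone.encode_bipartitions()
    clone.reroot_at_midpoint(update_bipartitions=True)
    return Phylogeny(clone)


def prune_join(
    t: Phylogeny, traits: Mapping[str, float], *, min_tips: int = 3
) -> tuple[Phylogeny, TipTraitMap]:
    """Restrict tree and trait map to their shared tips.

    Degree-2 nodes created by pruning are suppressed with branch lengths
    summed, so pairwise distances among retained tips are unchanged.
    """
    keep = sorted(set(t.tip_labels) & set(traits))
    if len(keep) < min_tips:
        raise ValueError(
            f"only {len(keep)} tips shared between tree and traits "
            f"(need >= {min_tips})"
        )
    clone = t.tree.clone(depth=1)
    clone.retain_taxa_with_labels(keep)
    pruned = Phylogeny(clone)
    values = {l: float(traits[l]) for l in keep}
    kind = "binary" if set(values.values()) <= {0.0, 1.0} else "continuous"
    return pruned, TipTraitMap(values=values, kind=kind)


def _root_depths(t: Phylogeny) -> dict:
    depths = {}
    for node in t.tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + node.edge.length
    return depths


def vcv_matrix(t: Phylogeny) -> pd.DataFrame:
    """Phylogenetic variance-covariance matrix (tips x tips).

    Entry (i, j) is the depth of the MRCA of tips i and j, i.e. the shared
    root-to-tip path length; the diagonal holds root-to-tip distances.
    Rows/columns follow :attr:`Phylogeny.tip_labels` order.
    """
    labels = t.tip_labels
    idx = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    V = np.zeros((n, n))
    depths = _root_depths(t)

    # postorder: collect tip indices per subtree; at each internal node the
    # covariance of tips in distinct child subtrees equals the node's depth
    tipsets: dict = {}
    for node in t.tree.postorder_node_iter():
        if node.is_leaf():
            i = idx[node.taxon.label]
            V[i, i] = depths[node]
            tipsets[node] = [i]
        else:
            groups = [tipsets.pop(c) for c in node.child_nodes()]
            d = depths[node]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    ia = np.asarray(groups[a])
                    ib = np.asarray(groups[b])
                    V[np.ix_(ia, ib)] = d
                    V[np.ix_(ib, ia)] = d
            tipsets[node] = [i for g in groups for i in g]
    return pd.DataFrame(V, index=labels, columns=labels)


def tip_distance_matrix(t: Phylogeny) -> pd.DataFrame:
    """Patristic (path-length) distances between all tip pairs."""
    labels = t.tip_labels
    pdm = t.tree.phylogenetic_distance_matrix()
    taxa = {tx.label: tx for tx in t.tree.taxon_namespace if tx.label in set(labels)}
    n = len(labels)
    D = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[a], taxa[labels[j]])
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=labels, columns=labels)
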