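"""Informative-locus selection, Cavalli-Sforza chord distance, and
neighbor-joining tree construction.

The panel is inbred, so at each locus a cultivar's allele-frequency vector is
a unit vector and the per-locus Cavalli-Sforza & Edwards chord distance
(2/pi) * sqrt(2 * (1 - sum_a sqrt(x_a * y_a))) collapses to 0 for concordant
calls and (2/pi) * sqrt(2) for discordant ones. Pairwise distances average
the per-locus values over co-scored loci (pairwise deletion of missing
data). Neighbor joining follows the standard Q-criterion agglomeration with
lexicographic tie-breaking and negative branch estimates clamped to zero
(deficit shifted to the sister branch); trees are scikit-bio TreeNode
objects with Newick serialization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .errors import InvalidParameterError, UndefinedStatisticError
from .genotyping import ALT, MISSING, REF, GenotypeMatrix

__all__ = [
    "MAX_CHORD",
    "DistanceMatrix",
    "select_informative",
    "chord_distance",
    "neighbor_joining",
    "random_additive_tree",
    "tree_tip_distances",
]

#: chord distance between fully discordant homozygotes, (2/pi) * sqrt(2)
MAX_CHORD = (2.0 / math.pi) * math.sqrt(2.0)


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal distances with per-pair co-scored locus counts."""

    ids: list[str]
    values: np.ndarray
    co_scored: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise InvalidParameterError("distance matrix shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def select_informative(gm: GenotypeMatrix, min_scored: int = 23) -> GenotypeMatrix:
    """Keep loci with non-missing calls in at least `min_scored` cultivars."""
    if min_scored > len(gm.cultivars):
        raise InvalidParameterError("min_scored exceeds the cultivar count")
    scored = (gm.calls.to_numpy() != MISSING).sum(axis=1)
    keep = scored >= min_scored
    if not keep.any():
        import warnings

        warnings.warn("no locus passes the informative-locus threshold", stacklevel=2)
    return gm.subset(keep)


def chord_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """Mean per-locus Cavalli-Sforza chord distance over co-scored loci."""
    cultivars = gm.cultivars
    if len(cultivars) < 2:
        raise InvalidParameterError("need at least two cultivars")
    calls = gm.calls.to_numpy()  # loci x cultivars
    n = len(cultivars)
    values = np.zeros((n, n))
    co = np.zeros((n, n), dtype=int)
    scored = calls != MISSING
    for i in range(n):
        for j in range(i + 1, n):
            both = scored[:, i] & scored[:, j]
            m = int(both.sum())
            co[i, j] = co[j, i] = m
            if m == 0:
                raise UndefinedStatisticError(
                    f"no co-scored loci for pair ({cultivars[i]}, {cultivars[j]})"
                )
            discordant = int((calls[both, i] != calls[both, j]).sum())
            d = MAX_CHORD * discordant / m
            values[i, j] = values[j, i] = d
    return DistanceMatrix(ids=list(cultivars), values=values, co_scored=co)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Standard neighbor joining; returns an unrooted tree (trifurcating root).

    At each step the pair minimizing Q(i,j) = (n-2) d(i,j) - r_i - r_j is
    joined (ties broken by the lexicographic order of the nodes' smallest
    leaf names), with limb lengths by the half-difference formulas. Negative
    limb estimates are clamped to zero with the deficit moved to the sister
    limb.
    """
    n = len(dm.ids)
    if n < 3:
        raise InvalidParameterError("neighbor joining needs at least three taxa")
    d = dm.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=name) for name in dm.ids]
    # sort key per working node: smallest leaf name underneath
    keys: list[str] = list(dm.ids)

    def _clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                tie_key = tuple(sorted((keys[i], keys[j])))
                if best is None or q < best[0] - 1e-12 or (abs(q - best[0]) <= 1e-12 and tie_key < best[1]):
                    best = (q, tie_key, i, j)
        _, _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = _clamp(li, lj)
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.extend([nodes[i], nodes[j]])
        new_key = min(keys[i], keys[j])
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_next = np.zeros((len(keep) + 1, len(keep) + 1))
        d_next[:-1, :-1] = d[np.ix_(keep, keep)]
        d_next[-1, :-1] = d_next[:-1, -1] = new_d[keep]
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [new_key]
        d = d_next

    # final three nodes joined at a trifurcating root (unrooted semantics)
    l0 = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    l1 = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    l2 = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    l0, l1, l2 = (max(x, 0.0) for x in (l0, l1, l2))
    root = TreeNode()
    for node, length in zip(nodes, (l0, l1, l2)):
        node.length = length
        root.append(node)
    return root


def tree_tip_distances(tree: TreeNode, ids: list[str]) -> np.ndarray:
    """Path-length (patristic) distance matrix between named tips."""
    skdm = tree.tip_tip_distances()
    idx = [list(skdm.ids).index(name) for name in ids]
    return np.asarray(skdm.data)[np.ix_(idx, idx)]


def random_additive_tree(
    n_taxa: int, rng: np.random.Generator, min_branch: float = 0.05, max_branch: float = 1.0
) -> tuple[TreeNode, DistanceMatrix]:
    """A random unrooted binary tree with positive branch lengths and its
    exact additive (patristic) distance matrix — the oracle for NJ recovery."""
    if n_taxa < 4:
        raise InvalidParameterError("need at least four taxa")
    names = [f"t{i}" for i in range(n_taxa)]

    def _leaf(name: str) -> TreeNode:
        node = TreeNode(name=name)
        node.length = float(rng.uniform(min_branch, max_branch))
        return node

    # grow by splitting random pendant edges of a 3-star
    root = TreeNode()
    root.extend([_leaf(names[0]), _leaf(names[1]), _leaf(names[2])])
    for name in names[3:]:
        tips = list(root.tips())
        target = tips[int(rng.integers(0, len(tips)))]
        inner = TreeNode()
        inner.length = float(rng.uniform(min_branch, max_branch))
        parent = target.parent
        parent.remove(target)
        inner.extend([target, _leaf(name)])
        parent.append(inner)
    dvals = tree_tip_distances(root, names)
    return root, DistanceMatrix(ids=names, values=dvals, co_scored=np.full((n_taxa, n_taxa), 1))
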