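"""Vectorized equal-rates-Markov (ERM) forest simulation.

The Monte-Carlo nulls need very many ERM topologies of a fixed tip count.
Building node objects for each would dominate runtime, so this module grows
whole *forests* as flat integer arrays, one batch of trees at a time:

* growth is ERM tip-splitting (at every step a uniformly chosen extant tip
  speciates), which induces the uniform-split law at every internal node;
* node ids are assigned in creation order, so every child id exceeds its
  parent id and a single reverse-id sweep performs all bottom-up passes;
* from the resulting ``left/right/parent`` arrays we extract, fully
  vectorized, the whole-tree imbalance indices and the per-branch local
  triplets (outgroup size, two basal ingroup sizes) feeding the shift
  statistic.

All arrays are shaped ``(n_trees, 2 * n_tips - 1)``; callers chunk batches
to bound memory.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

__all__ = [
    "erm_forest",
    "forest_index_stats",
    "forest_triplets",
    "tree_to_arrays",
    "ForestStats",
]


def tree_to_arrays(root) -> tuple[np.ndarray, np.ndarray, np.ndarray, list]:
    """Flatten one strictly bifurcating tree into single-row forest arrays.

    Nodes are renumbered in preorder (parent before children, root = 0) so the
    arrays satisfy the reverse-id sweep invariant. Returns
    ``(left, right, parent, nodes)`` where ``nodes[i]`` is the tree node at
    array index ``i`` and the arrays have shape ``(1, n_nodes)``.
    """
    nodes = []
    stack = [root]
    while stack:
        node = stack.pop()
        nodes.append(node)
        stack.extend(reversed(node.children))
    index = {id(n): i for i, n in enumerate(nodes)}
    n = len(nodes)
    left = np.full((1, n), -1, dtype=np.int32)
    right = np.full((1, n), -1, dtype=np.int32)
    parent = np.full((1, n), -1, dtype=np.int32)
    for i, node in enumerate(nodes):
        if node.children:
            if len(node.children) != 2:
                raise ValueError("tree_to_arrays requires a strictly bifurcating tree")
            left[0, i] = index[id(node.children[0])]
            right[0, i] = index[id(node.children[1])]
        if i > 0:
            parent[0, i] = index[id(node.parent)]
    return left, right, parent, nodes


def erm_forest(
    n_tips: int, n_trees: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Grow ``n_trees`` ERM topologies of ``n_tips`` tips.

    Returns ``(left, right, parent)`` int32 arrays of shape
    ``(n_trees, 2 * n_tips - 1)``; ``left[t, i] == -1`` marks a tip, the root
    is node 0 and ``parent[t, 0] == -1``.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    n_nodes = 2 * n_tips - 1
    left = np.full((n_trees, n_nodes), -1, dtype=np.int32)
    right = np.full((n_trees, n_nodes), -1, dtype=np.int32)
    parent = np.full((n_trees, n_nodes), -1, dtype=np.int32)
    rows = np.arange(n_trees)

    # node 0 = root with tip children 1, 2
    left[:, 0] = 1
    right[:, 0] = 2
    parent[:, 1] = 0
    parent[:, 2] = 0
    tips = np.empty((n_trees, n_tips), dtype=np.int32)
    tips[:, 0] = 1
    tips[:, 1] = 2

    for k in range(2, n_tips):
        j = rng.integers(0, k, size=n_trees)
        chosen = tips[rows, j]
        a, b = 2 * k - 1, 2 * k
        left[rows, chosen] = a
        right[rows, chosen] = b
        parent[:, a] = chosen
        parent[:, b] = chosen
        tips[rows, j] = a
        tips[:, k] = b
    return left, right, parent


def _bottom_up(left: np.ndarray, right: np.ndarray):
    """Tip counts and maximum edge-depths below every node (reverse-id sweep)."""
    n_trees, n_nodes = left.shape
    tipcount = np.ones((n_trees, n_nodes), dtype=np.int32)
    maxdepth = np.zeros((n_trees, n_nodes), dtype=np.int32)
    for idx in range(n_nodes - 1, -1, -1):
        rows = np.flatnonzero(left[:, idx] >= 0)
        if rows.size == 0:
            continue
        l = left[rows, idx]
        r = right[rows, idx]
        tipcount[rows, idx] = tipcount[rows, l] + tipcount[rows, r]
        maxdepth[rows, idx] = 1 + np.maximum(maxdepth[rows, l], maxdepth[rows, r])
    return tipcount, maxdepth


class ForestStats(NamedTuple):
    ic: np.ndarray  # Colless index per tree (int64)
    b1: np.ndarray  # B1 balance index per tree
    mpi: np.ndarray  # mean per-node log ERM split probability (nodes with >=3 tips)
    msig: np.ndarray  # population SD of the same log probabilities


def forest_index_stats(left: np.ndarray, right: np.ndarray) -> ForestStats:
    """Whole-tree symmetry indices (IC, B1, MPI*, Msigma*) per tree."""
    tipcount, maxdepth = _bottom_up(left, right)
    internal = left >= 0
    lidx = np.where(internal, left, 0)
    ridx = np.where(internal, right, 0)
    tc_l = np.take_along_axis(tipcount, lidx, axis=1)
    tc_r = np.take_along_axis(tipcount, ridx, axis=1)

    ic = np.where(internal, np.abs(tc_l - tc_r), 0).sum(axis=1, dtype=np.int64)

    nonroot_internal = internal.copy()
    nonroot_internal[:, 0] = False
    with np.errstate(divide="ignore"):
        inv_depth = np.where(nonroot_internal, 1.0 / np.maximum(maxdepth, 1), 0.0)
    b1 = inv_depth.sum(axis=1)

    # per-node ERM split probability: 2/(n-1) for unequal splits, 1/(n-1) for
    # equal ones; only nodes with >= 3 descendant tips carry shape information
    informative = internal & (tipcount >= 3)
    logp = np.where(tc_l != tc_r, np.log(2.0), 0.0) - np.log(
        np.maximum(tipcount - 1, 1)
    )
    logp = np.where(informative, logp, 0.0)
    count = informative.sum(axis=1)
    count_safe = np.maximum(count, 1)
    mean = logp.sum(axis=1) / count_safe
    var = np.where(informative, (logp - mean[:, None]) ** 2, 0.0).sum(axis=1) / count_safe
    return ForestStats(ic=ic, b1=b1, mpi=mean, msig=np.sqrt(var))


def forest_triplets(
    left: np.ndarray, right: np.ndarray, parent: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Local triplets for every eligible branch of every tree.

    A branch is eligible when its child node is internal and not the root.
    Returns flat int32 arrays ``(n_total, n_ingroup, n_left)`` where
    ``n_total`` includes the outgroup clade (the sibling at the branch's
    parent), ``n_ingroup`` the branch's child clade and ``n_left`` one of the
    child's two basal clades.
    """
    tipcount, _ = _bottom_up(left, right)
    internal = left >= 0
    eligible = internal.copy()
    eligible[:, 0] = False
    rows, cols = np.nonzero(eligible)
    n_in = tipcount[rows, cols]
    n_tot = tipcount[rows, parent[rows, cols]]
    n_l = tipcount[rows, left[rows, cols]]
    return n_tot, n_in, n_l
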