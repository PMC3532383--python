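"""Whole-tree symmetry statistics with an equal-rates-Markov Monte-Carlo null.

Four topology-based indices summarize how unevenly a clade has diversified:

``IC``
    the Colless index, sum over internal nodes of ``|l - r|`` where ``l`` and
    ``r`` are the two daughter tip counts; larger = more imbalanced.
``B1``
    sum over non-root internal nodes of ``1 / M_i`` where ``M_i`` is the
    maximum edge-count path from the node to any descendant tip; larger =
    more balanced.
``MPI`` / ``MSIG``
    mean and population standard deviation of the per-node log ERM split
    probability ``ln p_i`` over internal nodes with >= 3 descendant tips,
    where ``p_i = 2/(n_i - 1)`` for an unequal split and ``1/(n_i - 1)`` for
    an equal one (the uniform-split law of the ERM model). Cherries carry no
    shape information and are excluded.

Significance is calibrated against ERM topologies of the same tip count:
under equal rates every extant lineage is equally likely to split, so the
ingroup split size at each node is uniform. Observed trees may contain soft
polytomies; those are averaged over random ERM-consistent binary resolutions
and the report carries the 2.5%/97.5% quantiles across resolutions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _erm
from .composite import resolve_polytomies
from .treeio import Node, PhyloTree, TreeError

__all__ = [
    "colless_index",
    "b1_index",
    "nodal_logprob_stats",
    "simulate_erm_tree",
    "simulate_null_stats",
    "whole_tree_test",
    "IndexResult",
    "ImbalanceReport",
    "INDEX_TAILS",
]

#: tail direction of the one-sided test toward imbalance, per index
INDEX_TAILS = {"IC": "greater", "MSIG": "greater", "B1": "lesser", "MPI": "lesser"}

_NULL_CHUNK_CELLS = 8_000_000  # target cells per simulation chunk (memory bound)


def _require_bifurcating(tree: PhyloTree, op: str) -> None:
    if not tree.is_binary:
        raise TreeError(
            f"{op} is defined on strictly bifurcating trees; resolve soft "
            "polytomies first (composite.resolve_polytomies)"
        )


def _tip_counts(tree: PhyloTree) -> dict[int, int]:
    counts: dict[int, int] = {}
    for node in tree.postorder():
        counts[node.id] = 1 if node.is_tip else sum(counts[c.id] for c in node.children)
    return counts


def colless_index(tree: PhyloTree) -> int:
    """Colless imbalance IC = sum over internal nodes of |l - r|.

    Ranges from 0 (fully balanced) to (n-1)(n-2)/2 (caterpillar).
    """
    _require_bifurcating(tree, "colless_index")
    counts = _tip_counts(tree)
    return int(
        sum(
            abs(counts[n.children[0].id] - counts[n.children[1].id])
            for n in tree.internal_nodes()
        )
    )


def b1_index(tree: PhyloTree) -> float:
    """B1 balance index: sum over non-root internal nodes of 1/max-depth."""
    _require_bifurcating(tree, "b1_index")
    if tree.n_tips < 3:
        raise TreeError("b1_index needs at least 3 tips")
    depth: dict[int, int] = {}
    for node in tree.postorder():
        depth[node.id] = 0 if node.is_tip else 1 + max(depth[c.id] for c in node.children)
    return float(
        sum(1.0 / depth[n.id] for n in tree.internal_nodes() if n is not tree.root)
    )


def nodal_logprob_stats(tree: PhyloTree) -> tuple[float, float]:
    """(MPI, MSIG): mean and population SD of per-node log ERM split probability.

    Only internal nodes with >= 3 descendant tips contribute; MPI <= 0 and
    MSIG >= 0. The product of the per-node probabilities over *all* internal
    nodes is the ERM probability of the tree's labeled shape history.
    """
    _require_bifurcating(tree, "nodal_logprob_stats")
    if tree.n_tips < 4:
        raise TreeError("nodal_logprob_stats needs at least 4 tips")
    counts = _tip_counts(tree)
    logps = []
    for node in tree.internal_nodes():
        n_i = counts[node.id]
        if n_i < 3:
            continue
        l, r = (counts[c.id] for c in node.children)
        p = (1.0 if l == r else 2.0) / (n_i - 1)
        logps.append(math.log(p))
    arr = np.asarray(logps)
    return float(arr.mean()), float(arr.std())  # population SD


# ---------------------------------------------------------------------------
# ERM simulation
# ---------------------------------------------------------------------------


def simulate_erm_tree(n_tips: int, seed: int | np.random.Generator) -> PhyloTree:
    """One ERM topology of ``n_tips`` tips, by iterated uniform tip splitting.

    Starting from a cherry, at each step a uniformly chosen extant tip
    speciates; labels ``t1..tn`` are shuffled onto the tips afterwards so the
    distribution over labeled topologies is exactly ERM. Topology only (no
    ages); deterministic given the seed.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root = Node(0)
    nodes = [root]
    tree = PhyloTree(root, nodes)
    tips = [tree.new_node(parent=root), tree.new_node(parent=root)]
    for k in range(2, n_tips):
        j = int(rng.integers(0, k))
        chosen = tips[j]
        a = tree.new_node(parent=chosen)
        b = tree.new_node(parent=chosen)
        tips[j] = a
        tips.append(b)
    labels = [f"t{i + 1}" for i in range(n_tips)]
    for tip, lab in zip(tips, rng.permutation(labels)):
        tip.label = str(lab)
    return tree


def simulate_null_stats(
    n_tips: int, n_null: int, rng: np.random.Generator
) -> _erm.ForestStats:
    """Index statistics for ``n_null`` ERM trees of ``n_tips`` tips (chunked)."""
    chunk = max(1, min(n_null, _NULL_CHUNK_CELLS // (2 * n_tips - 1)))
    parts = []
    done = 0
    while done < n_null:
        t = min(chunk, n_null - done)
        left, right, _ = _erm.erm_forest(n_tips, t, rng)
        parts.append(_erm.forest_index_stats(left, right))
        done += t
    return _erm.ForestStats(*(np.concatenate(cols) for cols in zip(*parts)))


# ---------------------------------------------------------------------------
# Whole-tree test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IndexResult:
    """One index of an :class:`ImbalanceReport`.

    ``low``/``high`` are the 2.5%/97.5% quantiles of the observed index over
    polytomy resolutions (or the min/max when the report was built with
    ``extremes=True``); ``p_low``/``p_high`` the same quantiles of the
    per-resolution Monte-Carlo p-values.
    """

    index: str
    low: float
    high: float
    p_low: float
    p_high: float


@dataclass
class ImbalanceReport:
    results: dict[str, IndexResult]
    n_resolutions: int
    n_null: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "index": r.index,
                    "low": r.low,
                    "high": r.high,
                    "p_low": r.p_low,
                    "p_high": r.p_high,
                }
                for r in self.results.values()
            ]
        )

    def __getitem__(self, index: str) -> IndexResult:
        return self.results[index]


def _stats_for_tree(tree: PhyloTree) -> dict[str, float]:
    left, right, _, _ = _erm.tree_to_arrays(tree.root)
    s = _erm.forest_index_stats(left, right)
    return {"IC": float(s.ic[0]), "B1": float(s.b1[0]), "MPI": float(s.mpi[0]),
            "MSIG": float(s.msig[0])}


def _mc_pvalues(null: np.ndarray, obs: np.ndarray, tail: str) -> np.ndarray:
    """(1 + exceedances) / (1 + replicates); ties count as exceedances."""
    null = np.sort(null)
    n = null.size
    if tail == "greater":
        exceed = n - np.searchsorted(null, obs, side="left")
    else:
        exceed = np.searchsorted(null, obs, side="right")
    return (1.0 + exceed) / (1.0 + n)


def whole_tree_test(
    tree: PhyloTree,
    indices: tuple[str, ...] = ("IC", "MPI", "MSIG", "B1"),
    n_null: int = 10_000,
    n_resolutions: int = 1_000,
    seed: int | None = None,
    extremes: bool = False,
    null: _erm.ForestStats | None = None,
) -> ImbalanceReport:
    """Test a tree (polytomies allowed) against the ERM equal-rates null.

    One shared null sample of ``n_null`` ERM trees of the same tip count is
    simulated; the observed tree is resolved ``n_resolutions`` times (once if
    already bifurcating) and each index is tested one-tailed toward
    imbalance: greater tail for IC and MSIG, lesser tail for B1 and MPI.
    p-values follow the add-one convention ``(1 + exceedances)/(1 + n_null)``.
    A prebuilt null (:func:`simulate_null_stats` for the same tip count) may
    be passed to share one null sample across many trees.
    """
    bad = set(indices) - set(INDEX_TAILS)
    if bad:
        raise ValueError(f"unknown indices: {sorted(bad)}")
    if n_null < 100:
        raise ValueError("n_null < 100 gives too coarse a p-value resolution")
    rng = np.random.default_rng(seed)
    if null is None:
        null = simulate_null_stats(tree.n_tips, n_null, rng)
    n_null = null.ic.size
    null_by_index = {"IC": null.ic.astype(float), "B1": null.b1,
                     "MPI": null.mpi, "MSIG": null.msig}

    n_res = n_resolutions if not tree.is_binary else 1
    if n_res < 1:
        raise ValueError("n_resolutions must be >= 1")
    obs_rows = []
    for _ in range(n_res):
        resolved = resolve_polytomies(tree, seed=int(rng.integers(0, 2**31 - 1)))
        obs_rows.append(_stats_for_tree(resolved))
    obs = {k: np.array([row[k] for row in obs_rows]) for k in INDEX_TAILS}

    results = {}
    for name in indices:
        vals = obs[name]
        pvals = _mc_pvalues(null_by_index[name], vals, INDEX_TAILS[name])
        if extremes:
            lo, hi = float(vals.min()), float(vals.max())
            plo, phi = float(pvals.min()), float(pvals.max())
        else:
            lo, hi = (float(q) for q in np.quantile(vals, [0.025, 0.975]))
            plo, phi = (float(q) for q in np.quantile(pvals, [0.025, 0.975]))
        results[name] = IndexResult(name, lo, hi, plo, phi)
    return ImbalanceReport(results, n_res, n_null, seed)
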