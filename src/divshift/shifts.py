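"""Per-branch diversification-rate-shift statistic (Delta1) and its
Monte-Carlo significance scan.

For every internal branch whose child node is itself internal, the local
evidence for a rate shift along that branch is computed from a three-clade
summary: the outgroup clade at the branch's parent (``n_O`` tips) and the two
basal-most clades of the branch's child (``n_L``, ``n_R`` tips).

Under the homogeneous equal-rates-Markov (ERM) null, the ingroup size ``i``
of a node with ``n`` descendants is uniform on ``{1..n-1}``. Under a
one-shift two-rate alternative the ingroup-size law becomes a truncated
geometric ``P(i | n, r) = r**i / sum_j r**j``. The per-node shift evidence is
the maximized log likelihood ratio

    node_shift_loglr(n, i) = ln[ sup_r P(i | n, r) / (1/(n-1)) ],

which is 0 at a central split and exactly ``ln(n-1)`` at the boundaries
``i in {1, n-1}``. The branch statistic

    Delta1 = node_shift_loglr(n, n_I) - node_shift_loglr(n_I, n_L)

isolates the shift evidence carried by the branch itself: total evidence at
the inclusive node minus the part attributable to the nodal split below it.
Significance comes from Monte-Carlo simulation of ERM topologies of the same
tip count, either pooling Delta1 over all eligible branches of the null
trees (the default) or conditioning on the branch's inclusive clade size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _erm
from .composite import resolve_polytomies
from .treeio import Node, PhyloTree, TreeError

__all__ = [
    "DiversityTriplet",
    "ShiftResult",
    "ShiftReport",
    "ShiftNull",
    "local_triplet",
    "node_shift_loglr",
    "delta1",
    "build_shift_null",
    "scan_shifts",
    "count_sdr",
]


# ---------------------------------------------------------------------------
# the shift statistic
# ---------------------------------------------------------------------------


def _loglr_vec(n: np.ndarray, i: np.ndarray) -> np.ndarray:
    """Vectorized node_shift_loglr over integer arrays (no validation).

    The supremum over the truncated-geometric rate ratio ``r`` is found by
    bisection on the monotone mean-ingroup-size equation ``E_r[j] = i``; the
    reflection ``i <-> n - i`` maps ``r <-> 1/r``, so only ``r <= 1`` is ever
    solved and the statistic is exactly symmetric.
    """
    n = np.asarray(n, dtype=np.int64)
    i = np.asarray(i, dtype=np.int64)
    m = (n - 1).astype(np.float64)
    ic = np.minimum(i, n - i).astype(np.float64)
    out = np.zeros(n.shape, dtype=np.float64)

    boundary = (ic == 1) & (n > 2)
    out[boundary] = np.log(m[boundary])

    solve = (n > 2) & (ic > 1) & (2 * np.minimum(i, n - i) != n)
    if not np.any(solve):
        return out
    ms = m[solve]
    ks = ic[solve]
    lo = np.full(ms.shape, -40.0)
    hi = np.full(ms.shape, -1e-12)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        r = np.exp(mid)
        rm = r**ms
        mean = (1.0 - (ms + 1.0) * rm + ms * rm * r) / ((1.0 - r) * (1.0 - rm))
        too_small = mean < ks
        lo = np.where(too_small, mid, lo)
        hi = np.where(too_small, hi, mid)
    x = 0.5 * (lo + hi)
    r = np.exp(x)
    log_s = x + np.log1p(-(r**ms)) - np.log1p(-r)
    out[solve] = ks * x - log_s + np.log(ms)
    return np.maximum(out, 0.0)


def node_shift_loglr(n: int, i: int) -> float:
    """Maximized log likelihood ratio for a rate shift at one node.

    ``n`` is the node's total descendant tip count and ``i`` the size of one
    daughter clade; symmetric in ``i <-> n - i``, zero when ``n == 2`` and
    exactly ``ln(n-1)`` at ``i in {1, n-1}``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 1 <= i <= n - 1:
        raise ValueError(f"i must be in 1..{n - 1}, got {i}")
    return float(_loglr_vec(np.array([n]), np.array([i]))[0])


@dataclass(frozen=True)
class DiversityTriplet:
    """Tip counts of a local triplet anchored on an internal branch."""

    branch_id: int
    n_O: int  # outgroup clade (sibling at the branch's parent)
    n_L: int  # one basal clade of the branch's child
    n_R: int  # the other basal clade

    def __post_init__(self):
        if min(self.n_O, self.n_L, self.n_R) < 1:
            raise ValueError("all triplet counts must be >= 1")

    @property
    def n_I(self) -> int:
        return self.n_L + self.n_R

    @property
    def n(self) -> int:
        return self.n_O + self.n_I


def local_triplet(tree: PhyloTree, branch: Node | int) -> DiversityTriplet:
    """The (outgroup, basal-left, basal-right) tip counts for one branch.

    ``branch`` is identified by its child node; that node must be internal
    and must not be the root, and the tree must be strictly bifurcating.
    """
    node = tree.nodes[branch] if isinstance(branch, int) else branch
    if node.is_tip:
        raise TreeError("no triplet on a branch subtending a tip")
    if node.parent is None:
        raise TreeError("no triplet on the root")
    if len(node.children) != 2 or len(node.parent.children) != 2:
        raise TreeError("local_triplet requires a strictly bifurcating neighborhood")
    counts: dict[int, int] = {}
    stack = [node.parent]
    order = []
    while stack:
        cur = stack.pop()
        order.append(cur)
        stack.extend(cur.children)
    for cur in reversed(order):
        counts[cur.id] = 1 if cur.is_tip else sum(counts[c.id] for c in cur.children)
    sib = next(c for c in node.parent.children if c is not node)
    l, r = node.children
    return DiversityTriplet(node.id, counts[sib.id], counts[l.id], counts[r.id])


def delta1(triplet: DiversityTriplet) -> float:
    """Branch-localized shift statistic (may be negative when the nodal split
    is more extreme than the inclusive one); invariant under n_L <-> n_R."""
    return node_shift_loglr(triplet.n, triplet.n_I) - node_shift_loglr(
        triplet.n_I, triplet.n_L
    )


def _delta1_vec(n_tot: np.ndarray, n_in: np.ndarray, n_l: np.ndarray) -> np.ndarray:
    """Delta1 for many triplets at once, de-duplicating repeated (n, i) pairs."""

    def pairs(n, i):
        key = n.astype(np.int64) * (int(n.max()) + 1) + i.astype(np.int64)
        uniq, inv = np.unique(key, return_inverse=True)
        base = int(n.max()) + 1
        vals = _loglr_vec(uniq // base, uniq % base)
        return vals[inv]

    return pairs(n_tot, n_in) - pairs(n_in, n_l)


# ---------------------------------------------------------------------------
# Monte-Carlo null
# ---------------------------------------------------------------------------


@dataclass
class ShiftNull:
    """Pooled Delta1 null sample from ERM topologies of one tip count.

    ``values`` holds Delta1 for every eligible branch of every simulated
    tree, sorted ascending; ``n_in`` (aligned with ``values``) holds the
    inclusive clade size of each branch, for the size-conditional mode.
    """

    n_tips: int
    n_trees: int
    values: np.ndarray
    n_in: np.ndarray
    _cond: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    def pvalues(self, obs: np.ndarray, n_in_obs: np.ndarray | None, mode: str) -> np.ndarray:
        """Upper-tail add-one Monte-Carlo p-values for observed Delta1."""
        obs = np.atleast_1d(np.asarray(obs, dtype=np.float64))
        if mode == "pooled":
            total = self.values.size
            exceed = total - np.searchsorted(self.values, obs, side="left")
            return (1.0 + exceed) / (1.0 + total)
        if mode != "size-conditional":
            raise ValueError(f"unknown null mode {mode!r}")
        if n_in_obs is None:
            raise ValueError("size-conditional mode needs inclusive clade sizes")
        out = np.empty(obs.shape)
        for j, (v, sz) in enumerate(zip(obs, np.atleast_1d(n_in_obs))):
            grp = self._group(int(sz))
            if grp.size == 0:  # no null branch of that size: fall back to pooled
                grp = self.values
            exceed = grp.size - np.searchsorted(grp, v, side="left")
            out[j] = (1.0 + exceed) / (1.0 + grp.size)
        return out

    def _group(self, size: int) -> np.ndarray:
        if size not in self._cond:
            self._cond[size] = np.sort(self.values[self.n_in == size])
        return self._cond[size]


def build_shift_null(
    n_tips: int,
    n_null: int,
    seed: int | np.random.Generator | None,
    chunk_cells: int = 8_000_000,
) -> ShiftNull:
    """Simulate ``n_null`` ERM topologies and pool Delta1 over their branches."""
    if n_null < 100:
        raise ValueError("n_null < 100 cannot discriminate at alpha = 0.05")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    chunk = max(1, min(n_null, chunk_cells // (2 * n_tips - 1)))
    vals, sizes = [], []
    done = 0
    while done < n_null:
        t = min(chunk, n_null - done)
        left, right, parent = _erm.erm_forest(n_tips, t, rng)
        n_tot, n_in, n_l = _erm.forest_triplets(left, right, parent)
        vals.append(_delta1_vec(n_tot, n_in, n_l).astype(np.float32))
        sizes.append(n_in.astype(np.int32))
        done += t
    values = np.concatenate(vals).astype(np.float64)
    n_in = np.concatenate(sizes)
    order = np.argsort(values, kind="stable")
    return ShiftNull(n_tips, n_null, values[order], n_in[order])


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ShiftResult:
    """Shift statistic for one internal branch (medians across resolutions)."""

    branch_id: int
    clade: str  # fingerprint: smallest tip label + clade size
    n_O: int
    n_L: int
    n_R: int
    delta1: float
    p: float
    klass: str  # significant | marginal | nonsignificant
    delta1_low: float = math.nan  # 2.5% quantile across polytomy resolutions
    delta1_high: float = math.nan  # 97.5% quantile


@dataclass
class ShiftReport:
    results: list[ShiftResult]
    n_resolutions: int
    n_null: int
    null_mode: str
    seed: int | None

    def __iter__(self):
        return iter(self.results)

    def __len__(self) -> int:
        return len(self.results)

    def significant(self) -> list[ShiftResult]:
        return [r for r in self.results if r.klass == "significant"]

    def marginal(self) -> list[ShiftResult]:
        return [r for r in self.results if r.klass == "marginal"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "branch_id": r.branch_id,
                    "clade_name": r.clade,
                    "n_O": r.n_O,
                    "n_L": r.n_L,
                    "n_R": r.n_R,
                    "delta1": r.delta1,
                    "p": r.p,
                    "class": r.klass,
                    "delta1_low": r.delta1_low,
                    "delta1_high": r.delta1_high,
                }
                for r in self.results
            ]
        )


def _classify(p: float, alpha_inclusive: bool) -> str:
    if p < 0.05 or (alpha_inclusive and p <= 0.05):
        return "significant"
    if p < 0.10:
        return "marginal"
    return "nonsignificant"


def _clade_fingerprints(tree: PhyloTree) -> dict[int, str]:
    """Smallest tip label + clade size per node, as a stable clade identifier."""
    smallest: dict[int, str] = {}
    size: dict[int, int] = {}
    for node in tree.postorder():
        if node.is_tip:
            smallest[node.id] = node.label
            size[node.id] = 1
        else:
            smallest[node.id] = min(smallest[c.id] for c in node.children)
            size[node.id] = sum(size[c.id] for c in node.children)
    return {nid: f"{smallest[nid]}+{size[nid]}" for nid in smallest}


def scan_shifts(
    tree: PhyloTree,
    n_null: int = 10_000,
    n_resolutions: int = 100,
    null_mode: str = "pooled",
    seed: int | None = None,
    alpha_inclusive: bool = False,
    null: ShiftNull | None = None,
) -> ShiftReport:
    """Delta1 scan over every eligible internal branch of ``tree``.

    Polytomies are treated as soft: the tree is resolved ``n_resolutions``
    times (once if already bifurcating) and each *input-tree* branch reports
    the median Delta1 and median p across resolutions, plus 2.5%/97.5%
    quantiles. ``null`` may carry a prebuilt :class:`ShiftNull` of the same
    tip count to share one null sample across many scans; otherwise one is
    simulated from ``n_null`` ERM topologies. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    n_tips = tree.n_tips
    if null is None:
        null = build_shift_null(n_tips, n_null, rng)
    elif null.n_tips != n_tips:
        raise ValueError(
            f"null was built for {null.n_tips} tips but the tree has {n_tips}"
        )

    branches = [
        n for n in tree.preorder() if not n.is_tip and n.parent is not None
    ]
    if not branches:
        return ShiftReport([], 0, null.n_trees, null_mode, seed)
    branch_ids = [n.id for n in branches]
    fingerprints = _clade_fingerprints(tree)

    n_res = n_resolutions if not tree.is_binary else 1
    if n_res < 1:
        raise ValueError("n_resolutions must be >= 1")
    d1 = np.empty((n_res, len(branches)))
    pv = np.empty((n_res, len(branches)))
    first_triplets: list[tuple[int, int, int]] | None = None
    for res in range(n_res):
        resolved = (
            tree
            if tree.is_binary
            else resolve_polytomies(tree, seed=int(rng.integers(0, 2**31 - 1)))
        )
        left, right, parent, nodes = _erm.tree_to_arrays(resolved.root)
        tipcount, _ = _erm._bottom_up(left, right)
        idx_of = {node.id: i for i, node in enumerate(nodes)}
        bidx = np.array([idx_of[b] for b in branch_ids])
        n_in = tipcount[0, bidx]
        n_tot = tipcount[0, parent[0, bidx]]
        n_l = tipcount[0, left[0, bidx]]
        if first_triplets is None:
            first_triplets = [
                (int(t - i), int(l), int(i - l)) for t, i, l in zip(n_tot, n_in, n_l)
            ]
        d1[res] = _delta1_vec(n_tot, n_in, n_l)
        pv[res] = null.pvalues(d1[res], n_in, null_mode)

    med_d1 = np.median(d1, axis=0)
    med_p = np.median(pv, axis=0)
    lo, hi = np.quantile(d1, [0.025, 0.975], axis=0)
    results = [
        ShiftResult(
            branch_id=bid,
            clade=fingerprints[bid],
            n_O=trip[0],
            n_L=trip[1],
            n_R=trip[2],
            delta1=float(med_d1[j]),
            p=float(med_p[j]),
            klass=_classify(float(med_p[j]), alpha_inclusive),
            delta1_low=float(lo[j]),
            delta1_high=float(hi[j]),
        )
        for j, (bid, trip) in enumerate(zip(branch_ids, first_triplets))
    ]
    return ShiftReport(results, n_res, null.n_trees, null_mode, seed)


# ---------------------------------------------------------------------------
# per-clade shift counting
# ---------------------------------------------------------------------------


def count_sdr(
    results: list[ShiftResult] | ShiftReport,
    clades: dict[str, set[str]],
    tree: PhyloTree,
) -> pd.DataFrame:
    """Count significant and marginal shifts per named clade.

    ``clades`` maps clade names to tip-label sets (which must be nested or
    disjoint); each shift is assigned to the smallest named clade containing
    its branch's tip set. Shifts contained in no named clade are dropped.
    """
    names = list(clades)
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            sa, sb = clades[names[a]], clades[names[b]]
            inter = sa & sb
            if inter and inter != sa and inter != sb:
                raise ValueError(
                    f"clades {names[a]!r} and {names[b]!r} overlap without nesting"
                )
    tips = set(tree.tip_labels())
    for name, s in clades.items():
        if not s <= tips:
            raise ValueError(f"clade {name!r} contains labels absent from the tree")

    counts = pd.DataFrame(0, index=names, columns=["significant", "marginal"])
    node_by_id = {n.id: n for n in tree.preorder()}
    items = results.results if isinstance(results, ShiftReport) else results
    for res in items:
        if res.klass == "nonsignificant":
            continue
        clade_tips = tree.clade_tip_labels(node_by_id[res.branch_id])
        holders = [nm for nm in names if clade_tips <= clades[nm]]
        if not holders:
            continue
        smallest = min(holders, key=lambda nm: len(clades[nm]))
        counts.loc[smallest, res.klass] += 1
    return counts
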