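"""Shared test utilities: deterministic tree builders and oracles."""

from __future__ import annotations

from fractions import Fraction
from functools import lru_cache

import numpy as np

import divshift as ds


def caterpillar(n: int) -> ds.PhyloTree:
    """Fully imbalanced (pectinate) n-tip tree."""
    s = "(a0,a1)"
    for i in range(2, n):
        s = f"({s},a{i})"
    return ds.parse_newick(s + ";")


def balanced(n: int) -> ds.PhyloTree:
    """Fully balanced tree; n must be a power of two."""
    assert n & (n - 1) == 0

    def build(labels):
        if len(labels) == 1:
            return labels[0]
        h = len(labels) // 2
        return f"({build(labels[:h])},{build(labels[h:])})"

    return ds.parse_newick(build([f"b{i}" for i in range(n)]) + ";")


def clade_multiset(tree: ds.PhyloTree) -> list:
    """Sorted list of internal-node tip-label sets: a topology fingerprint."""
    return sorted(
        tuple(sorted(tree.clade_tip_labels(n))) for n in tree.internal_nodes()
    )


def isomorphic(t1: ds.PhyloTree, t2: ds.PhyloTree) -> bool:
    return clade_multiset(t1) == clade_multiset(t2)


@lru_cache(maxsize=None)
def exact_ic_distribution(n: int) -> tuple[tuple[int, Fraction], ...]:
    """Exact ERM null distribution of the Colless index, by enumeration.

    Independent oracle: recursive convolution over the uniform ingroup-size
    law (ordered split size uniform on 1..n-1), exact in rational arithmetic.
    """
    if n <= 2:
        return ((0, Fraction(1)),)
    dist: dict[int, Fraction] = {}
    w = Fraction(1, n - 1)
    for i in range(1, n):
        for ic_l, p_l in exact_ic_distribution(i):
            for ic_r, p_r in exact_ic_distribution(n - i):
                ic = abs(n - 2 * i) + ic_l + ic_r
                dist[ic] = dist.get(ic, Fraction(0)) + w * p_l * p_r
    return tuple(sorted(dist.items()))


def loglr_oracle(n: int, i: int) -> float:
    """Brute-force maximization of the truncated-geometric likelihood ratio.

    Independent of the bisection path: evaluates the profile log-likelihood
    on a dense log-rate grid refined around its maximum.
    """
    j = np.arange(1, n)

    def profile(log_r: np.ndarray) -> np.ndarray:
        # i*log r - logsumexp(j*log r), stable for any sign of log r
        a = j[None, :] * log_r[:, None]
        amax = a.max(axis=1)
        return i * log_r - (amax + np.log(np.exp(a - amax[:, None]).sum(axis=1)))

    lo, hi = -60.0, 60.0
    for _ in range(8):
        grid = np.linspace(lo, hi, 400)
        vals = profile(grid)
        k = int(np.argmax(vals))
        lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, grid.size - 1)]
    best = profile(np.array([(lo + hi) / 2])).max()
    return float(best + np.log(n - 1))


def enumerate_shapes(n: int):
    """All rooted binary tree shapes of n tips as canonical nested tuples."""
    if n == 1:
        return [1]
    out = []
    seen = set()
    for i in range(1, n // 2 + 1):
        for a in enumerate_shapes(i):
            for b in enumerate_shapes(n - i):
                key = tuple(sorted((repr(a), repr(b))))
                if key in seen:
                    continue
                seen.add(key)
                out.append((a, b))
    return out


def shape_to_tree(shape) -> ds.PhyloTree:
    counter = [0]

    def nwk(s):
        if s == 1:
            counter[0] += 1
            return f"x{counter[0]}"
        return f"({nwk(s[0])},{nwk(s[1])})"

    return ds.parse_newick(nwk(shape) + ";")
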