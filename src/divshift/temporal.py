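"""Epoch-binned temporal analysis of the shift statistic on a dated tree.

Each branch's |Delta1| is attributed to a dated node (by default the
branch's child, the inclusive node), nodes are binned into geological
epochs, and the per-epoch means are compared with a one-way fixed-effects
ANOVA followed by Tukey HSD pairwise comparisons. This asks whether shift
evidence is concentrated in particular geological intervals — e.g. whether
Paleogene nodes carry more or less signal than Neogene ones.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .shifts import ShiftReport, ShiftResult
from .treeio import EpochTable, PhyloTree, TreeError

__all__ = [
    "assign_epoch",
    "anova_tukey",
    "epoch_shift_summary",
    "AnovaResult",
    "EpochSummary",
]

log = logging.getLogger(__name__)


def assign_epoch(age: float, epochs: EpochTable) -> str:
    """Name of the epoch containing ``age`` (Mya).

    Intervals are half-open with the shared boundary belonging to the
    *younger* epoch (an age equal to an epoch's older bound falls inside that
    epoch); the youngest epoch is closed at 0.
    """
    if age < 0:
        raise ValueError(f"negative age: {age}")
    if age > epochs.oldest:
        raise ValueError(
            f"age {age} Mya predates the oldest epoch bound ({epochs.oldest} Mya)"
        )
    for epoch in epochs:
        if epoch.younger < age <= epoch.older:
            return epoch.name
    return epochs.epochs[-1].name  # age == 0


class AnovaResult(NamedTuple):
    F: float
    df1: int
    df2: int
    p: float


def anova_tukey(groups: dict[str, Iterable[float]]) -> tuple[AnovaResult, pd.DataFrame]:
    """One-way fixed-effects ANOVA plus Tukey HSD over named samples.

    Empty groups are dropped with a warning. When every value is identical
    the F statistic is 0 and all adjusted p-values are 1. The Tukey table has
    columns ``group1, group2, meandiff, p_adj`` (studentized-range adjusted).
    """
    clean = {k: np.asarray(list(v), dtype=float) for k, v in groups.items()}
    empty = [k for k, v in clean.items() if v.size == 0]
    if empty:
        warnings.warn(f"dropping empty group(s): {empty}", stacklevel=2)
        for k in empty:
            del clean[k]
    k = len(clean)
    if k < 2:
        raise ValueError("ANOVA needs at least 2 non-empty groups")
    n_total = sum(v.size for v in clean.values())
    if n_total <= k:
        raise ValueError("ANOVA needs more observations than groups")
    df1, df2 = k - 1, n_total - k

    values = np.concatenate(list(clean.values()))
    labels = np.concatenate([np.repeat(name, v.size) for name, v in clean.items()])
    pairs = list(combinations(sorted(clean), 2))

    if np.ptp(values) == 0:
        tukey = pd.DataFrame(
            [(a, b, 0.0, 1.0) for a, b in pairs],
            columns=["group1", "group2", "meandiff", "p_adj"],
        )
        return AnovaResult(0.0, df1, df2, 1.0), tukey

    f_stat, p = stats.f_oneway(*clean.values())
    if not np.isfinite(f_stat):  # zero within-group variance, distinct means
        f_stat, p = float("inf"), 0.0

    res = pairwise_tukeyhsd(values, labels)
    # statsmodels orders groups with np.unique and pairs (i, j), i < j, which
    # matches combinations() over the sorted names
    tukey = pd.DataFrame(
        {
            "group1": [a for a, _ in pairs],
            "group2": [b for _, b in pairs],
            "meandiff": res.meandiffs,
            "p_adj": res.pvalues,
        }
    )
    return AnovaResult(float(f_stat), df1, df2, float(p)), tukey


@dataclass
class EpochSummary:
    """Per-epoch |Delta1| summary plus the across-epoch ANOVA/Tukey results."""

    per_epoch: pd.DataFrame  # epoch, n_nodes, mean_abs_delta1, sd
    anova: AnovaResult
    tukey: pd.DataFrame
    n_values: int


def epoch_shift_summary(
    tree: PhyloTree,
    results: list[ShiftResult] | ShiftReport,
    epochs: EpochTable,
    nodes: str = "eligible",
    attribution: str = "child",
    skip_undated: bool = False,
) -> EpochSummary:
    """Bin |Delta1| by the epoch of each statistic's node and compare epochs.

    ``results`` must come from a scan of ``tree`` itself (branch ids are node
    ids of that tree), and the tree must be dated. ``attribution`` picks the
    node whose age bins the branch: its child end (``"child"``, the inclusive
    node) or its parent end. ``nodes="all"`` additionally includes every
    internal non-root dated node without a triplet (their branches subtend
    cherries' tips and carry |Delta1| = 0); ``nodes="eligible"`` uses only
    branches with a computed statistic. Undated nodes raise unless
    ``skip_undated`` is set, in which case they are excluded and logged.
    """
    if not tree.has_ages:
        raise TreeError("epoch binning requires a dated tree")
    if nodes not in ("eligible", "all"):
        raise ValueError("nodes must be 'eligible' or 'all'")
    if attribution not in ("child", "parent"):
        raise ValueError("attribution must be 'child' or 'parent'")

    node_by_id = {n.id: n for n in tree.preorder()}
    items = list(results.results if isinstance(results, ShiftReport) else results)

    entries: list[tuple[float, float]] = []  # (age, |delta1|)
    seen_ids: set[int] = set()
    skipped = 0
    for res in items:
        node = node_by_id[res.branch_id]
        seen_ids.add(node.id)
        anchor = node if attribution == "child" else node.parent
        if anchor.age is None:
            if skip_undated:
                skipped += 1
                continue
            raise TreeError(
                f"node {anchor.id} carries a shift statistic but has no age"
            )
        entries.append((anchor.age, abs(res.delta1)))
    if nodes == "all":
        for node in tree.internal_nodes():
            if node is tree.root or node.id in seen_ids:
                continue
            anchor = node if attribution == "child" else node.parent
            if anchor.age is None:
                if skip_undated:
                    skipped += 1
                    continue
                raise TreeError(f"internal node {anchor.id} has no age")
            entries.append((anchor.age, 0.0))
    if skipped:
        log.info("epoch_shift_summary: excluded %d undated node(s)", skipped)

    groups: dict[str, list[float]] = {e.name: [] for e in epochs}
    for age, val in entries:
        groups[assign_epoch(age, epochs)].append(val)

    per_epoch = pd.DataFrame(
        [
            {
                "epoch": name,
                "n_nodes": len(vals),
                "mean_abs_delta1": float(np.mean(vals)) if vals else np.nan,
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
            }
            for name, vals in groups.items()
        ]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty epochs are expected on small trees
        anova, tukey = anova_tukey(groups)
    return EpochSummary(per_epoch, anova, tukey, len(entries))
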