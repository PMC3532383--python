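"""Composite-topology construction: grafting unsampled species, soft-polytomy
resolution and taxon-coverage accounting.

A molecular phylogeny rarely samples every recognized species. To run
shape-based diversification statistics on the *complete* species list, each
species without molecular data is grafted onto the most recent common
ancestor (MRCA) of the sampled members of its lowest-ranked taxonomic group
with at least one sampled member, searched genus -> tribe/subfamily ->
family. Grafting onto a single sampled relative creates a new cherry; onto a
multi-member group it adds a child at the group MRCA, creating or extending a
polytomy. Such polytomies encode placement uncertainty and are soft: the
statistics average over random ERM-consistent binary resolutions.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .treeio import Node, PhyloTree, TaxonomyTable, TaxonomyError, TreeError

__all__ = [
    "GraftResult",
    "graft_missing_species",
    "resolve_polytomies",
    "coverage_summary",
]


class GraftResult(NamedTuple):
    """Outcome of :func:`graft_missing_species`."""

    tree: PhyloTree  # composite topology (sampled + grafted tips)
    grafted: list[str]  # species added, in processing order
    ungraftable: list[str]  # species whose family has no sampled member


def graft_missing_species(tree: PhyloTree, taxonomy: TaxonomyTable) -> GraftResult:
    """Graft every graftable unsampled species onto the molecular tree.

    Each missing species is attached at the MRCA of the *sampled* members of
    its lowest-ranked group with >= 1 sampled member (genus, then
    tribe/subfamily, then family); multiple missing members of one group join
    the same attachment node, forming a single soft polytomy. Species whose
    family has no sampled member are returned as ungraftable. Grafted nodes
    carry ``origin == "grafted"``; the topology induced on the original tips
    is never altered.
    """
    if len(taxonomy) == 0:  # pragma: no cover - TaxonomyTable forbids this
        raise TaxonomyError("empty taxonomy")
    tip_set = set(tree.tip_labels())
    tax_species = set(taxonomy.species)
    stray = tip_set - tax_species
    if stray:
        raise TreeError(f"tree tips absent from taxonomy: {sorted(stray)[:5]}")
    unplaced_sampled = set(taxonomy.sampled_species()) - tip_set
    if unplaced_sampled:
        raise TreeError(
            "taxonomy marks species as sampled that are not tips: "
            f"{sorted(unplaced_sampled)[:5]}"
        )

    out = tree.copy()
    tipmap = out.tip_map()
    df = taxonomy.frame
    sampled_by_group: dict[tuple[str, str], list[str]] = {}
    for rank in ("genus", "tribe", "family"):
        sub = df.loc[df["sampled"] & df[rank].notna()]
        for value, block in sub.groupby(rank, sort=False):
            sampled_by_group[(rank, value)] = block["species"].tolist()

    attach_cache: dict[tuple[str, str], Node] = {}
    grafted: list[str] = []
    ungraftable: list[str] = []
    missing = df.loc[~df["sampled"]].sort_values("species")

    for row in missing.itertuples():
        target: Node | None = None
        for rank, value in (
            ("genus", row.genus),
            ("tribe", row.tribe),
            ("family", row.family),
        ):
            if pd.isna(value):
                continue
            key = (rank, value)
            members = sampled_by_group.get(key)
            if not members:
                continue
            if key in attach_cache:
                target = attach_cache[key]
            else:
                target = out.mrca([tipmap[m] for m in members])
                if target.is_tip:
                    # single sampled relative: insert a cherry node above it
                    tip = target
                    grand = tip.parent
                    joint = out.new_node()
                    joint.origin = "grafted"
                    joint.parent = grand
                    if grand is not None:
                        grand.children[grand.children.index(tip)] = joint
                    else:  # pragma: no cover - 1-tip trees are rejected upstream
                        out.root = joint
                    tip.parent = joint
                    joint.children.append(tip)
                    target = joint
                attach_cache[key] = target
            break
        if target is None:
            ungraftable.append(row.species)
            continue
        new_tip = out.new_node(label=row.species, parent=target)
        new_tip.origin = "grafted"
        tipmap[row.species] = new_tip
        grafted.append(row.species)

    out.validate()
    return GraftResult(out, grafted, ungraftable)


def resolve_polytomies(tree: PhyloTree, seed: int) -> PhyloTree:
    """Replace every polytomy by a uniformly random ERM-consistent resolution.

    Each degree-k polytomy is resolved into one of the binary labeled
    histories an equal-rates Markov growth over its k child subtrees would
    produce, all with equal probability over the resulting labeled shapes.
    Existing nodes keep their identity (ids) and relative arrangement; the
    inserted nodes get fresh ids and no ages. Deterministic given ``seed``;
    an already binary tree comes back topologically unchanged.
    """
    rng = np.random.default_rng(seed)
    out = tree.copy()
    for node in list(out.preorder()):
        k = len(node.children)
        if k <= 2:
            continue
        order = [node.children[i] for i in rng.permutation(k)]
        node.children = order[:2]
        for child in order[:2]:
            child.parent = node
        slots = order[:2]
        for incoming in order[2:]:
            j = int(rng.integers(0, len(slots)))
            slot = slots[j]
            holder = slot.parent
            joint = out.new_node()
            joint.origin = node.origin
            joint.parent = holder
            holder.children[holder.children.index(slot)] = joint
            slot.parent = joint
            incoming.parent = joint
            joint.children = [slot, incoming]
            slots.append(incoming)
    out.validate()
    return out


def _pct(sampled: int, recognized: int) -> int:
    """Percentage rounded to the nearest integer (half away from zero)."""
    if recognized == 0:
        return 0
    return int(np.floor(100.0 * sampled / recognized + 0.5))


def coverage_summary(
    taxonomy: TaxonomyTable,
    groups: list[tuple[str, str]] | None = None,
    total_label: str = "TOTAL",
) -> pd.DataFrame:
    """Genus- and species-level sampling coverage per taxonomic group.

    ``groups`` lists (rank, name) pairs; by default every major clade and
    every family gets a row. A grand-total row over the whole taxonomy is
    always appended. A genus counts as sampled when at least one of its
    species has molecular data; percentages are rounded to the nearest
    integer.
    """
    df = taxonomy.frame
    if groups is None:
        groups = [("clade", c) for c in df["clade"].unique()]
        groups += [("family", f) for f in df["family"].unique()]
    rows = []
    for rank, name in groups:
        if rank not in ("genus", "tribe", "family", "clade"):
            raise TaxonomyError(f"unknown rank {rank!r}")
        block = df.loc[df[rank] == name]
        if block.empty:
            raise TaxonomyError(f"unknown group {name!r} at rank {rank!r}")
        rows.append(_coverage_row(name, rank, block))
    rows.append(_coverage_row(total_label, "all", df))
    return pd.DataFrame(rows)


def _coverage_row(name: str, rank: str, block: pd.DataFrame) -> dict:
    n_gen = block["genus"].nunique()
    n_gen_s = block.loc[block["sampled"], "genus"].nunique()
    n_sp = len(block)
    n_sp_s = int(block["sampled"].sum())
    return {
        "group": name,
        "rank": rank,
        "n_genera": n_gen,
        "n_genera_sampled": n_gen_s,
        "genus_coverage_pct": _pct(n_gen_s, n_gen),
        "n_species": n_sp,
        "n_species_sampled": n_sp_s,
        "species_coverage_pct": _pct(n_sp_s, n_sp),
    }
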