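"""Synthetic data with the statistical structure the pipeline assumes.

Three generators make every stage testable without external data:

* :func:`simulate_yule_dated` -- a pure-birth (Yule) chronogram; its
  topology marginal is exactly the equal-rates-Markov law the imbalance and
  shift nulls assume, and its node ages feed the temporal stage.
* :func:`plant_rate_shift` -- a two-rate pure-birth tree in which one
  lineage, chosen at a configured time, and all its descendants speciate at
  ``s`` times the background rate; the shifted branch is returned as ground
  truth for power studies of the Delta1 scan.
* :func:`simulate_taxonomy_and_sampling` -- a nested taxonomy built by
  cutting the chronogram at increasing heights (genera at a young cut,
  families older, major clades older still — every group monophyletic by
  construction) plus independent per-species sampling, emulating the
  partially sampled species lists that drive grafting.

All generators take explicit seeds; none touches global random state.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .treeio import Node, PhyloTree, TaxonomyTable

__all__ = [
    "SimConfig",
    "simulate_yule_dated",
    "plant_rate_shift",
    "simulate_taxonomy_and_sampling",
    "taxonomy_from_counts",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the generators.

    ``birth_rate`` is per lineage per Myr; 0.1/Myr puts ~2,000 species in
    ~70 Myr, the scale of a large Cenozoic mammal radiation. The default
    ``sampling_fraction`` of 0.56 emulates a molecular matrix covering a bit
    over half the recognized species. ``shift_time`` is measured in Myr after
    the root split; ``None`` places the shift at 30% of the expected tree
    depth ``ln(n/2) / birth_rate``. The rank cuts are fractions of the root
    age at which the tree is sliced into genera, tribes, families and major
    clades (young to old).
    """

    n_tips: int = 256
    birth_rate: float = 0.1
    shift_multiplier: float = 1.0
    shift_time: float | None = None
    sampling_fraction: float = 0.56
    genus_cut: float = 0.22
    tribe_cut: float = 0.40
    family_cut: float = 0.60
    clade_cut: float = 0.87
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be positive")
        if self.shift_multiplier < 0:
            raise ValueError("shift_multiplier must be >= 0")
        if not 0 < self.sampling_fraction <= 1:
            raise ValueError("sampling_fraction must be in (0, 1]")
        cuts = (self.genus_cut, self.tribe_cut, self.family_cut, self.clade_cut)
        if not all(0 < c < 1 for c in cuts) or list(cuts) != sorted(cuts):
            raise ValueError("rank cuts must increase in (0, 1), young to old")


def taxonomy_from_counts(
    rows: list[tuple[str, str, int, int, int, int]]
) -> TaxonomyTable:
    """Build a species-level taxonomy realizing published summary counts.

    Each row is ``(clade, family, n_genera, n_genera_sampled, n_species,
    n_species_sampled)``; placeholder genus and species names are generated
    so that exactly ``n_genera_sampled`` genera contain sampled species and
    exactly ``n_species_sampled`` species are sampled. Useful for exercising
    coverage accounting against published per-group tallies without species
    lists.
    """
    records = []
    for clade, family, n_gen, g_s, n_sp, sp_s in rows:
        if not (1 <= n_gen <= n_sp and 0 <= g_s <= n_gen and 0 <= sp_s <= n_sp):
            raise ValueError(f"inconsistent counts for {family}")
        if (g_s == 0 and sp_s > 0) or sp_s < g_s or (n_sp - sp_s) < (n_gen - g_s):
            raise ValueError(
                f"{family}: cannot place {sp_s} sampled species in exactly "
                f"{g_s} of {n_gen} genera"
            )
        # one seed species per genus (sampled for the first g_s genera),
        # remaining species and sampled flags absorbed by the first genus
        sp_idx = 0
        extra_sampled = sp_s - g_s
        extra_total = n_sp - n_gen
        for g in range(n_gen):
            genus = f"{family}_g{g + 1}"
            n_here = 1 + (extra_total if g == 0 else 0)
            for k in range(n_here):
                sp_idx += 1
                if g == 0:
                    sampled = (g_s > 0 and k == 0) or (1 <= k <= extra_sampled)
                else:
                    sampled = g < g_s
                records.append(
                    {
                        "species": f"{family}_sp{sp_idx}",
                        "genus": genus,
                        "tribe": pd.NA,
                        "family": family,
                        "clade": clade,
                        "sampled": sampled,
                    }
                )
    return TaxonomyTable(pd.DataFrame(records))


def _grow(
    n_tips: int,
    lam: float,
    s: float,
    shift_time: float | None,
    rng: np.random.Generator,
) -> tuple[PhyloTree, Node | None]:
    """One two-rate pure-birth tree; returns (tree, shifted lineage node)."""
    root = Node(0)
    tree = PhyloTree(root, [root])
    split_time: dict[int, float] = {root.id: 0.0}
    active = [tree.new_node(parent=root), tree.new_node(parent=root)]
    mult = [1.0, 1.0]
    t = 0.0
    shift_node: Node | None = None
    pending = shift_time is not None

    while True:
        total = lam * sum(mult)
        dt = rng.exponential(1.0 / total) if total > 0 else math.inf
        if pending and t + dt > shift_time:
            # apply the shift exactly at shift_time (exponential memorylessness
            # lets us simply restart the waiting time from there)
            t = shift_time
            j = int(rng.integers(0, len(active)))
            mult[j] = s
            shift_node = active[j]
            pending = False
            continue
        t += dt
        if len(active) == n_tips:
            break  # t is now the stopping time just past the last split
        weights = np.asarray(mult) / sum(mult)
        j = int(rng.choice(len(active), p=weights))
        node = active[j]
        split_time[node.id] = t
        a = tree.new_node(parent=node)
        b = tree.new_node(parent=node)
        active[j] = a
        active.append(b)
        mult.append(mult[j])

    for node in tree.preorder():
        node.age = 0.0 if node.is_tip else t - split_time[node.id]
    labels = rng.permutation([f"sp{i + 1:04d}" for i in range(n_tips)])
    for tip, lab in zip(active, labels):
        tip.label = str(lab)
    tree.validate()
    return tree, shift_node


def simulate_yule_dated(
    n_tips: int, birth_rate: float, seed: int | np.random.Generator
) -> PhyloTree:
    """A dated pure-birth tree grown to ``n_tips`` extant species.

    At ``k`` lineages the waiting time to the next speciation is
    Exponential(k * birth_rate); ages are in Myr with tips at 0. The topology
    marginal is ERM. Deterministic given the seed.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tree, _ = _grow(n_tips, birth_rate, 1.0, None, rng)
    return tree


def plant_rate_shift(
    config: SimConfig, max_retries: int = 1000
) -> tuple[PhyloTree, int]:
    """A dated tree with a planted diversification-rate shift.

    At ``config.shift_time`` Myr after the root split one extant lineage is
    chosen uniformly; it and its descendants thereafter speciate at
    ``shift_multiplier * birth_rate``. Returns the tree and the node id of
    the shifted lineage (the ground-truth branch). Replicates in which the
    tree reaches ``n_tips`` before the shift time are resampled, with the
    retry count logged.
    """
    rng = np.random.default_rng(config.seed)
    shift_time = config.shift_time
    if shift_time is None:
        shift_time = 0.3 * math.log(config.n_tips / 2) / config.birth_rate
    retries = 0
    while True:
        tree, node = _grow(
            config.n_tips, config.birth_rate, config.shift_multiplier, shift_time, rng
        )
        if node is not None:
            break
        retries += 1
        if retries > max_retries:
            raise RuntimeError(
                f"shift time {shift_time} Myr was never reached before "
                f"{config.n_tips} tips in {max_retries} attempts"
            )
    if retries:
        log.info("plant_rate_shift: resampled %d time(s)", retries)
    return tree, node.id


def simulate_taxonomy_and_sampling(
    tree: PhyloTree, config: SimConfig, seed: int | np.random.Generator
) -> tuple[TaxonomyTable, PhyloTree]:
    """Cluster tips into nested ranks and subsample species with molecular data.

    Ranks come from slicing the chronogram at ``genus_cut < tribe_cut <
    family_cut < clade_cut`` (fractions of the root age): each lineage
    crossing a cut height founds one group, so every group is monophyletic
    and ranks nest strictly. Each species is sampled independently with
    probability ``config.sampling_fraction``; the returned pruned tree keeps
    only sampled tips (ages preserved).
    """
    if not tree.has_ages:
        raise ValueError("taxonomy simulation requires a dated tree")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root_age = tree.root.age

    def groups_at(height: float, prefix: str) -> dict[str, str]:
        group_of: dict[int, int] = {}
        counter = 0
        for node in tree.preorder():
            parent_age = math.inf if node.parent is None else node.parent.age
            age = node.age if node.age is not None else 0.0
            if parent_age > height >= age:
                counter += 1
                group_of[node.id] = counter
            elif node.parent is None:
                group_of[node.id] = 0  # root above the cut; descendants cross later
            else:
                group_of[node.id] = group_of[node.parent.id]
        return {
            n.label: f"{prefix}{group_of[n.id]:04d}" for n in tree.tips()
        }

    genus = groups_at(config.genus_cut * root_age, "G")
    tribe = groups_at(config.tribe_cut * root_age, "T")
    family = groups_at(config.family_cut * root_age, "F")
    clade = groups_at(config.clade_cut * root_age, "C")

    species = sorted(genus)
    sampled_mask = rng.random(len(species)) < config.sampling_fraction
    frame = pd.DataFrame(
        {
            "species": species,
            "genus": [genus[s] for s in species],
            "tribe": [tribe[s] for s in species],
            "family": [family[s] for s in species],
            "clade": [clade[s] for s in species],
            "sampled": sampled_mask,
        }
    )
    taxonomy = TaxonomyTable(frame)
    sampled_species = taxonomy.sampled_species()
    if len(sampled_species) < 2:
        raise ValueError(
            "fewer than 2 species were sampled; raise sampling_fraction or n_tips"
        )
    pruned = tree.prune_to(sampled_species)
    return taxonomy, pruned
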