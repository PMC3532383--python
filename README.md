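# divshift

Tree-shape imbalance and diversification-rate-shift analysis for
species-level phylogenies.

Large molecular phylogenies rarely sample every recognized species, yet
questions about *how* a clade diversified — did some lineages speciate
faster than others, and when? — need the complete species-level topology.
`divshift` implements the full analysis pipeline used in large-radiation
studies (rodents, bats, birds): it grafts unsampled species onto a
molecular backbone using a ranked taxonomy, tests the resulting composite
tree for departure from an equal-rates null, localizes significant
diversification-rate shifts on individual branches, and bins the shift
evidence into geological epochs on a dated tree. A synthetic-data module
generates pure-birth chronograms, planted rate shifts and partially sampled
taxonomies, so every stage is testable with no external downloads.

## The statistics

All null calibration rests on the **equal-rates Markov (ERM)** model of
clade growth: at every moment each extant lineage is equally likely to
split, which makes the ingroup split size *i* at a node with *n* descendant
tips uniform on {1, …, n−1}.

**Whole-tree symmetry** is summarized by four indices, each tested against
Monte-Carlo ERM topologies of the same tip count:

- *I<sub>C</sub>* (Colless): Σ over internal nodes of |l − r|, the daughter
  tip-count differences (higher = more imbalanced);
- *B1*: Σ over non-root internal nodes of 1/M<sub>i</sub>, where
  M<sub>i</sub> is the maximum edge-count depth below node *i* (higher =
  more balanced);
- *M<sub>Π*</sub>*, *M<sub>σ*</sub>*: mean and population SD of the
  per-node log ERM split probability ln p<sub>i</sub>, with
  p<sub>i</sub> = 2/(n<sub>i</sub>−1) for an unequal split and
  1/(n<sub>i</sub>−1) for an equal one, over nodes with ≥ 3 tips.

**Per-branch shifts** use the Δ1 statistic on a local triplet — the
outgroup clade at the branch's parent (n<sub>O</sub> tips) plus the two
basal clades of the branch's child (n<sub>L</sub>, n<sub>R</sub>). With

&nbsp;&nbsp;Λ(n, i) = ln [ sup<sub>r</sub> P(i | n, r) / (1/(n−1)) ],
&nbsp;&nbsp;P(i | n, r) = r<sup>i</sup> / Σ<sub>j=1…n−1</sub> r<sup>j</sup>

(a truncated-geometric one-shift alternative against the uniform ERM law;
Λ(n, 1) = Λ(n, n−1) = ln(n−1) exactly), the branch statistic is

&nbsp;&nbsp;Δ1 = Λ(n<sub>O</sub>+n<sub>L</sub>+n<sub>R</sub>, n<sub>L</sub>+n<sub>R</sub>) − Λ(n<sub>L</sub>+n<sub>R</sub>, n<sub>L</sub>),

the shift evidence at the inclusive node minus the part explained by the
nodal split below it. Significance is the upper tail against Δ1 pooled over
all eligible branches of simulated ERM trees (size-conditional nulls are
available). Soft polytomies — e.g. those created by grafting — are averaged
over random ERM-consistent binary resolutions.

**Temporal structure**: each branch's |Δ1| is attributed to its dated
inclusive node, nodes are binned into geological epochs
(Paleocene … Quaternary by default), and per-epoch means are compared with
one-way ANOVA plus Tukey HSD.

## Worked example

```python
import divshift as ds

# a dated 300-species tree, a 56%-sampled taxonomy, and the molecular tree
tree = ds.simulate_yule_dated(300, birth_rate=0.1, seed=7)
taxonomy, molecular = ds.simulate_taxonomy_and_sampling(
    tree, ds.SimConfig(n_tips=300, sampling_fraction=0.56), seed=8)

# coverage accounting and the composite topology
total = ds.coverage_summary(taxonomy, groups=[]).iloc[-1]
print(int(total["n_species_sampled"]), "of", int(total["n_species"]),
      "species sampled:", int(total["species_coverage_pct"]), "%")
result = ds.graft_missing_species(molecular, taxonomy)
print(result.tree.n_tips, len(result.ungraftable))

# whole-tree imbalance and the shift scan on the composite
report = ds.whole_tree_test(result.tree, n_null=10_000,
                            n_resolutions=100, seed=42)
print(round(report["IC"].low), round(report["IC"].high),
      round(report["IC"].p_high, 3))
scan = ds.scan_shifts(result.tree, n_null=10_000,
                      n_resolutions=100, seed=42)
print(len(scan), len(scan.significant()))
```

prints

```
176 of 300 species sampled: 59 %
298 2
1498 1593 0.264
198 12
```

— 176 of 300 species (59%) carry molecular data; grafting restores the 124
missing species except 2 whose families have no sampled member, giving a
298-tip composite. Across 100 random resolutions of the grafting polytomies
the Colless index ranges 1498–1593 and is not significantly imbalanced for
this equal-rates simulation (p ≥ 0.264 at the 97.5% resolution quantile),
and the Δ1 scan flags 12 of 198 branches at α = 0.05 — chance level, as
expected when no shift was planted. Planting one (`ds.plant_rate_shift`)
makes the shifted branch the top-ranked Δ1 in most replicates.

The same stages are exposed as a CLI:
`divshift simulate|graft|coverage|imbalance|shifts|epochs --help`.

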