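# Methods

This note records the models behind `divshift`, the choices made where the
design was genuinely open, and what the synthetic tests do and do not
establish about real data.

## The equal-rates null and its simulation

Every significance statement in the package is calibrated against the
equal-rates Markov (ERM) model: clade growth in which, at each step, every
extant lineage is equally likely to split. ERM induces a uniform law for
the ordered ingroup split size at each internal node, and it is the
topology marginal of the continuous-time Yule (pure-birth) process, which
is why `simulate_yule_dated` can feed the same statistics with ages
attached. Extinction is deliberately absent: the null is pure ERM, and a
birth–death generator would change only the ages, not the topology law the
indices test against.

ERM forests for the Monte-Carlo nulls are grown as flat integer arrays
(`_erm.py`), one uniformly chosen tip splitting per step, with node ids in
creation order so a single reverse-id sweep computes all bottom-up
quantities. One null sample is simulated per tip count and shared across
polytomy resolutions and across trees when callers pass it explicitly; this
is exact because all resolutions of a tree have identical size.

## Whole-tree indices

* **Colless I_C** = Σ |l − r| over internal nodes (integer in
  [0, (n−1)(n−2)/2]).
* **B1** = Σ 1/M_i over non-root internal nodes, M_i the maximum
  edge-count depth below node i.
* **MΠ\*, Mσ\***: mean and *population* (divide-by-N) standard deviation of
  ln p_i over internal nodes with ≥ 3 descendant tips, where
  p_i = 2/(n_i − 1) for an unequal split and 1/(n_i − 1) for an equal one.
  The literature these summaries descend from does not fix a single
  normalization; this operationalization is committed here because cherries
  carry no shape information, the product of p_i over all internal nodes is
  exactly the ERM probability of the tree's shape (verified by complete
  shape enumeration for n ≤ 7 in the tests), and any monotone variant is
  equivalently calibrated by the Monte-Carlo null. Published magnitudes for
  a large rodent tree (means ≈ −0.9, SDs ≈ 0.6) are in the range this
  definition produces.

One-sided tests point toward imbalance: greater tail for I_C and Mσ\*,
lesser tail for B1 and MΠ\*. All Monte-Carlo p-values use the add-one
convention (1 + exceedances)/(1 + replicates), ties counted as exceedances,
so p is never 0.

## The Δ1 branch statistic

The shift statistic is a maximized log likelihood ratio on a local triplet.
Under homogeneous ERM the ingroup size i at a node with n tips is uniform,
P0(i|n) = 1/(n−1); under a one-shift two-rate alternative it follows a
truncated geometric P(i|n, r) = r^i / Σ_{j=1..n−1} r^j. The per-node
evidence Λ(n, i) = ln[sup_r P(i|n, r)/P0(i|n)] is found by bisection on the
monotone mean equation E_r[j] = i (closed-form geometric sums; the
reflection i ↔ n−i maps r ↔ 1/r, so only r ≤ 1 is solved and symmetry is
exact). Λ(n, 1) = Λ(n, n−1) = ln(n−1) exactly and Λ = 0 at a central
split. The branch statistic is

    Δ1 = Λ(n_O + n_I, n_I) − Λ(n_I, n_L),      n_I = n_L + n_R,

evidence at the inclusive node minus the part attributable to the nodal
split below the branch. This reconstruction matches the verbal description
of the original method (triplet-local, likelihood-based, branch-attributed)
and its boundary behavior, but the original algebra is unpublished; see
"Known limitations".

Null modes: **pooled** (default) compares each observed Δ1 against Δ1
pooled over every eligible branch of the simulated ERM trees; it mirrors
the classical procedure ("null topologies of the same size as the final
tree") but ignores clade-size dependence, so p-values are uniform only
marginally over branches. **size-conditional** restricts the null to
branches with the same inclusive clade size, at the cost of coarser
resolution for rare sizes (empty strata fall back to the pooled sample).

## Soft polytomies

Polytomies are stored natively and treated as uncertainty, never resolved
at parse time. `resolve_polytomies` replaces each degree-k multifurcation
by a uniformly random ERM-consistent labeled resolution (tip-splitting
growth over the k child subtrees with shuffled insertion order; for k = 3
each of the 3 shapes has probability 1/3, for k = 4 the 15 labeled shapes
follow the ERM law — both verified by simulation against enumeration).
Whole-tree and scan statistics report 2.5%/97.5% quantiles across
resolutions and the median as point estimate (the aggregation rule is a
package choice; the source procedure is unstated). The scan reports one
result per *input-tree* branch: nodes inserted by a resolution exist only
within that resolution and have no cross-resolution identity.

## Grafting

A species without molecular data attaches at the MRCA of the sampled
members of its lowest-ranked group with ≥ 1 sampled member, searched genus
→ tribe/subfamily → family — lowest rank first, the only reading consistent
with "closest relative". A single sampled relative yields a new cherry;
several missing members of one group join the same attachment node, forming
one soft polytomy rather than an arbitrary nested chain (no intra-group
order information exists). Grafted tips carry no ages: composite trees are
topology-only objects for the shift scan, and the temporal stage consumes
the dated molecular tree instead. Species whose family has no sampled
member are reported ungraftable and omitted. Grafting provably never
changes the topology induced on the original tips (tested by pruning the
composite back).

Coverage percentages are rounded half away from zero to the nearest
integer. Published tables of this kind often mix truncation and rounding;
the counts, not the printed percentages, are treated as authoritative.

## Temporal stage

Each branch's |Δ1| is attributed to a dated node — by default the child end
(the inclusive node, matching the "nodal" reading), configurable to the
parent end. Epoch intervals are half-open with shared boundaries belonging
to the younger epoch and the youngest epoch closed at 0; the bundled
Cenozoic table uses 23.03 Mya for the Oligocene/Miocene boundary (sources
print both 23.0 and 23.03; the finer figure is used). Binned values feed a
one-way fixed-effects ANOVA (scipy) and Tukey HSD (statsmodels). Because
tip-subtending branches have no triplet, a dated tree with n tips yields
n − 2 eligible values; `nodes="all"` additionally counts ineligible
internal nodes as |Δ1| = 0, covering the alternative convention large
published analyses appear to use (their degrees of freedom slightly exceed
the eligible-branch count).

## Synthetic data

The generators define the study conditions rather than adapting to them:
birth rate 0.1/lineage/Myr (≈ 2,000 species in ≈ 70 Myr, the scale of a
large Cenozoic radiation), sampling fraction 0.56 (a molecular matrix
covering just over half the recognized species), planted shifts applied to
one uniformly chosen lineage at 30% of the expected tree depth, and
taxonomy ranks cut at 0.22/0.40/0.60/0.87 of the root age — heights chosen
so a ~2,261-species tree yields genus, family and major-clade counts of
realistic magnitude (≈ 5 species per genus, a few dozen families, a
handful of major clades). All generators take explicit seeds and touch no
global state.

What the synthetic fixtures do *not* emulate: extinction, non-random
(clade-biased) sampling of molecular data, taxonomy that conflicts with the
tree (real genera are not always monophyletic), and dating error. Passing
tests therefore certify the statistics and their calibration under the
stated null, not robustness to those real-data violations.

## Numerical choices

* Ultrametricity tolerance for dated input: relative 1e−6 of tree height;
  ages round-trip through Newick within 1e−9.
* Λ bisection: 80 iterations on ln r ∈ [−40, 0), boundary cases (i ∈ {1,
  n−1}, central splits, n = 2) handled in closed form; agreement with a
  brute-force profile-likelihood grid oracle to 1e−6.
* Repeated (n, i) pairs in a scan are deduplicated before solving; the
  pooled null for a 2,263-tip tree at 10^4 replicates (~2.3 × 10^7 branch
  values) completes in well under a minute on one CPU, which is why the
  default test and acceptance problem sizes (10^4 null topologies, 100–200
  simulated trees, 40–60 power replicates) were chosen; the classical
  10^6-topology setting is supported by the same code path.
* Monte-Carlo p-values are never 0 by construction; n_null < 100 is
  rejected as too coarse for α = 0.05 work.

## Known limitations

* The exact algebra of the original Δ1 is unpublished in the source
  material; this package's truncated-geometric likelihood-ratio
  reconstruction reproduces its qualitative behavior and boundary values
  but not, in at least one fully determined case, its printed per-branch
  values (the determined squirrel-family branch computes 0.0036 here
  against a printed 2.25: a near-boundary inclusive node minus a
  near-boundary nodal split cancels under this algebra). Per-branch values
  from the two constructions are therefore not interchangeable, while the
  calibration properties (type-I error, p-uniformity, power monotonicity)
  are construction-independent and are the tested surface.
* In the planted-shift power study the ground-truth branch is an
  age-conditioned lineage, not a branch sampled like the pooled null
  population, so its detection rate at s = 1 sits near but slightly above
  the nominal α under the pooled null (≈ 0.08–0.10 at α = 0.05 in the
  bundled experiments). This is a property of the design, not a bug; the
  unconditional branch flag rate on ERM trees is at α.
* Tukey HSD p-values come from statsmodels' studentized-range
  implementation; with very small groups (n = 1) they are reported as
  computed, without small-sample correction.
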