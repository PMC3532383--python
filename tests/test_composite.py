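"""Grafting, soft-polytomy resolution and coverage accounting."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

import divshift as ds
from _helpers import clade_multiset, isomorphic


class TestGrafting:
    def test_single_relative_creates_cherry(self):
        tree = ds.parse_newick("((a1,c1),d1);")
        tax = ds.read_taxonomy(
            "species,genus,family,clade\n"
            "a1,A,F,X\na2,A,F,X\nc1,C,F,X\nd1,D,F,X\n",
            tip_labels=tree.tip_labels(),
        )
        result = ds.graft_missing_species(tree, tax)
        assert sorted(result.tree.tip_labels()) == ["a1", "a2", "c1", "d1"]
        a2 = result.tree.tip_map()["a2"]
        assert {c.label for c in a2.parent.children} == {"a1", "a2"}
        assert a2.origin == "grafted"

    def test_monophyletic_genus_gains_polytomy(self):
        tree = ds.parse_newick("((a1,a2),c1);")
        tax = ds.read_taxonomy(
            "species,genus,family,clade\n"
            "a1,A,F,X\na2,A,F,X\na3,A,F,X\nc1,C,F,X\n",
            tip_labels=tree.tip_labels(),
        )
        result = ds.graft_missing_species(tree, tax)
        a3 = result.tree.tip_map()["a3"]
        assert {c.label for c in a3.parent.children} == {"a1", "a2", "a3"}

    def test_rank_order_prefers_genus_then_tribe_then_family(self):
        tree = ds.parse_newick("((a1,b1),c1);")
        tax = ds.read_taxonomy(
            "species,genus,tribe,family,clade\n"
            "a1,A,T1,F,X\nb1,B,T1,F,X\nc1,C,T2,F,X\n"
            "b2,B,T1,F,X\nt1,Anew,T1,F,X\nf1,Cnew,T3,F,X\n",
            tip_labels=tree.tip_labels(),
        )
        result = ds.graft_missing_species(tree, tax)
        tips = result.tree.tip_map()
        # b2 shares genus B: cherry with b1
        assert {c.label for c in tips["b2"].parent.children} == {"b1", "b2"}
        # t1's genus is unsampled but tribe T1 = {a1, b1}: attach at their MRCA
        assert set(result.tree.clade_tip_labels(tips["t1"].parent)) >= {"a1", "b1", "t1"}
        # f1's genus and tribe are unsampled; family F spans everything
        assert tips["f1"].parent is result.tree.root or set(
            result.tree.clade_tip_labels(tips["f1"].parent)
        ) >= {"a1", "b1", "c1"}

    def test_ungraftable_family_reported_and_omitted(self, toy_tree, toy_taxonomy):
        result = ds.graft_missing_species(toy_tree, toy_taxonomy)
        assert result.ungraftable == ["d1"]
        assert "d1" not in result.tree.tip_labels()
        assert sorted(result.grafted) == ["a2", "a3"]

    def test_tip_missing_from_taxonomy_errors(self, toy_taxonomy):
        tree = ds.parse_newick("((a1,zz),c1);")
        with pytest.raises(ds.TreeError, match="zz"):
            ds.graft_missing_species(tree, toy_taxonomy)

    def test_induced_topology_on_original_tips_unchanged(self):
        tree = ds.simulate_yule_dated(120, 0.2, 3)
        taxonomy, pruned = ds.simulate_taxonomy_and_sampling(
            tree, ds.SimConfig(n_tips=120, sampling_fraction=0.5), 4
        )
        result = ds.graft_missing_species(pruned, taxonomy)
        induced = result.tree.prune_to(pruned.tip_labels())
        assert isomorphic(induced, pruned)

    def test_composite_tip_count_conservation(self):
        tree = ds.simulate_yule_dated(150, 0.2, 9)
        taxonomy, pruned = ds.simulate_taxonomy_and_sampling(
            tree, ds.SimConfig(n_tips=150, sampling_fraction=0.4), 10
        )
        result = ds.graft_missing_species(pruned, taxonomy)
        missing = len(taxonomy) - len(taxonomy.sampled_species())
        assert result.tree.n_tips == pruned.n_tips + missing - len(result.ungraftable)


class TestResolvePolytomies:
    def test_trichotomy_resolutions_uniform(self):
        tree = ds.parse_newick("((a,b,c),d);")
        counts = Counter()
        for seed in range(10_000):
            resolved = ds.resolve_polytomies(tree, seed)
            assert resolved.is_binary
            node = next(
                n
                for n in resolved.internal_nodes()
                if resolved.clade_tip_labels(n) == frozenset("abc")
            )
            basal = next(
                min(resolved.clade_tip_labels(c))
                for c in node.children
                if len(resolved.clade_tip_labels(c)) == 1
            )
            counts[basal] += 1
        for label in "abc":
            assert counts[label] / 10_000 == pytest.approx(1 / 3, abs=0.02)

    def test_degree_four_hits_all_fifteen_topologies(self):
        tree = ds.parse_newick("(a,b,c,d);")
        seen = Counter()
        for seed in range(20_000):
            resolved = ds.resolve_polytomies(tree, seed)
            seen[tuple(clade_multiset(resolved))] += 1
        assert len(seen) == 15  # all rooted binary shapes on 4 labels
        # ERM over labeled histories: each caterpillar 1/18, each balanced 1/9
        for shape, count in seen.items():
            # balanced shapes contain two cherries, caterpillars only one
            n_cherries = sum(1 for clade in shape if len(clade) == 2)
            expected = 1 / 9 if n_cherries == 2 else 1 / 18
            assert count / 20_000 == pytest.approx(expected, abs=0.015)

    def test_binary_tree_unchanged(self):
        tree = ds.simulate_erm_tree(30, 1)
        for seed in (0, 99):
            assert isomorphic(tree, ds.resolve_polytomies(tree, seed))

    def test_tip_multiset_preserved_below_polytomy(self):
        tree = ds.parse_newick("((a,b,c,d,e),(f,g));")
        resolved = ds.resolve_polytomies(tree, 5)
        assert frozenset("abcde") in {
            resolved.clade_tip_labels(n) for n in resolved.internal_nodes()
        }

    def test_deterministic_given_seed(self):
        tree = ds.parse_newick("((a,b,c,d,e),(f,g,h));")
        t1 = ds.resolve_polytomies(tree, 123)
        t2 = ds.resolve_polytomies(tree, 123)
        assert clade_multiset(t1) == clade_multiset(t2)


class TestCoverage:
    def test_percentages_and_totals(self, toy_taxonomy):
        report = ds.coverage_summary(toy_taxonomy, groups=[("family", "FA")])
        fa = report.iloc[0]
        assert fa["n_genera"] == 2 and fa["n_genera_sampled"] == 2
        assert fa["genus_coverage_pct"] == 100
        assert fa["n_species"] == 5 and fa["n_species_sampled"] == 3
        assert fa["species_coverage_pct"] == 60
        total = report.iloc[-1]
        assert total["group"] == "TOTAL"
        assert total["n_species"] == 7 and total["n_species_sampled"] == 4

    def test_fully_sampled_group_is_100(self):
        tax = ds.read_taxonomy(
            "species,genus,family,clade,sampled\n"
            "a,A,F,X,1\nb,A,F,X,1\nc,B,G,X,0\n"
        )
        report = ds.coverage_summary(tax, groups=[("family", "F")])
        assert report.iloc[0]["species_coverage_pct"] == 100

    def test_unknown_group_errors(self, toy_taxonomy):
        with pytest.raises(ds.TaxonomyError, match="unknown group"):
            ds.coverage_summary(toy_taxonomy, groups=[("family", "NOPE")])

    def test_sampled_never_exceeds_recognized(self):
        tree = ds.simulate_yule_dated(80, 0.2, 2)
        taxonomy, _ = ds.simulate_taxonomy_and_sampling(
            tree, ds.SimConfig(n_tips=80), 3
        )
        report = ds.coverage_summary(taxonomy)
        assert (report["n_genera_sampled"] <= report["n_genera"]).all()
        assert (report["n_species_sampled"] <= report["n_species"]).all()
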