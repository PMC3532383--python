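"""The Delta1 shift statistic, its Monte-Carlo null and the branch scan."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import divshift as ds
from divshift.shifts import _loglr_vec
from _helpers import balanced, loglr_oracle


class TestNodeShiftLoglr:
    def test_trivial_and_boundary_values(self):
        assert ds.node_shift_loglr(2, 1) == 0.0
        assert ds.node_shift_loglr(278, 277) == pytest.approx(math.log(277))
        assert ds.node_shift_loglr(278, 1) == pytest.approx(math.log(277))

    def test_near_central_split_carries_no_evidence(self):
        assert 0.0 <= ds.node_shift_loglr(277, 138) <= 0.01

    @pytest.mark.parametrize(
        "n,i",
        [(5, 2), (10, 3), (17, 5), (40, 7), (40, 19), (101, 33), (200, 60), (277, 100)],
    )
    def test_matches_brute_force_profile_likelihood(self, n, i):
        assert ds.node_shift_loglr(n, i) == pytest.approx(
            loglr_oracle(n, i), abs=1e-6
        )

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(min_value=2, max_value=400), st.data())
    def test_reflection_symmetry(self, n, data):
        i = data.draw(st.integers(min_value=1, max_value=n - 1))
        assert ds.node_shift_loglr(n, i) == ds.node_shift_loglr(n, n - i)

    @pytest.mark.parametrize("n", [5, 17, 64, 200])
    def test_nonincreasing_from_boundary_to_center(self, n):
        i = np.arange(1, n // 2 + 1)
        vals = _loglr_vec(np.full(i.shape, n), i)
        assert np.all(np.diff(vals) <= 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ds.node_shift_loglr(5, 0)
        with pytest.raises(ValueError):
            ds.node_shift_loglr(5, 5)


class TestLocalTriplet:
    def test_counts_from_neighborhood(self):
        tree = ds.parse_newick("(((a1,(a2,a3)),(b1,b2)),((c1,c2),(c3,c4)));")
        node = next(
            n
            for n in tree.internal_nodes()
            if tree.clade_tip_labels(n) == frozenset(["a1", "a2", "a3", "b1", "b2"])
        )
        trip = ds.local_triplet(tree, node)
        assert (trip.n_O, sorted([trip.n_L, trip.n_R])) == (4, [2, 3])
        assert trip.n_I == 5 and trip.n == 9

    def test_minimal_triplet(self):
        tree = ds.parse_newick("(((a,b),c),d);")
        node = next(
            n
            for n in tree.internal_nodes()
            if tree.clade_tip_labels(n) == frozenset("ab")
        )
        trip = ds.local_triplet(tree, node)
        assert (trip.n_O, trip.n_L, trip.n_R) == (1, 1, 1)

    def test_tip_branch_rejected(self):
        tree = ds.parse_newick("((a,b),c);")
        tip = tree.tip_map()["a"]
        with pytest.raises(ds.TreeError, match="tip"):
            ds.local_triplet(tree, tip)

    def test_root_rejected(self):
        tree = ds.parse_newick("((a,b),c);")
        with pytest.raises(ds.TreeError, match="root"):
            ds.local_triplet(tree, tree.root)


class TestDelta1:
    def test_minimal_triplet_value(self):
        assert ds.delta1(ds.DiversityTriplet(0, 1, 1, 1)) == pytest.approx(
            math.log(2)
        )

    def test_tiny_outgroup_near_boundary(self):
        val = ds.delta1(ds.DiversityTriplet(0, 1, 138, 139))
        assert val == pytest.approx(math.log(277), abs=0.01)

    @settings(derandomize=True, max_examples=100)
    @given(
        st.integers(min_value=1, max_value=300),
        st.integers(min_value=1, max_value=300),
        st.integers(min_value=1, max_value=300),
    )
    def test_symmetric_in_basal_clades(self, o, l, r):
        assert ds.delta1(ds.DiversityTriplet(0, o, l, r)) == pytest.approx(
            ds.delta1(ds.DiversityTriplet(0, o, r, l)), abs=1e-12
        )


class TestScan:
    def test_results_cover_eligible_branches(self):
        tree = ds.simulate_erm_tree(64, 3)
        report = ds.scan_shifts(tree, n_null=500, seed=4)
        eligible = [
            n
            for n in tree.internal_nodes()
            if n.parent is not None
        ]
        assert len(report) == len(eligible) == 62

    def test_balanced_tree_has_no_significant_branch(self):
        report = ds.scan_shifts(balanced(128), n_null=2000, seed=5)
        assert len(report.significant()) == 0

    def test_deterministic_given_seed(self):
        tree = ds.parse_newick("((a,b,c,d,e),((f,g),(h,i)));")
        r1 = ds.scan_shifts(tree, n_null=500, n_resolutions=30, seed=7)
        r2 = ds.scan_shifts(tree, n_null=500, n_resolutions=30, seed=7)
        assert r1.to_frame().equals(r2.to_frame())

    def test_label_permutation_invariance(self):
        tree = ds.simulate_erm_tree(40, 8)
        null = ds.build_shift_null(40, 500, 1)
        r1 = ds.scan_shifts(tree, null=null, seed=0)
        relabeled = tree.copy()
        rng = np.random.default_rng(2)
        tips = relabeled.tips()
        labels = rng.permutation([t.label for t in tips])
        for tip, lab in zip(tips, labels):
            tip.label = str(lab)
        r2 = ds.scan_shifts(relabeled, null=null, seed=0)
        assert [r.delta1 for r in r1] == [r.delta1 for r in r2]
        assert [r.p for r in r1] == [r.p for r in r2]

    def test_size_conditional_mode_runs_and_bounds_p(self):
        tree = ds.simulate_erm_tree(64, 9)
        report = ds.scan_shifts(tree, n_null=1000, null_mode="size-conditional", seed=3)
        assert all(0 < r.p <= 1 for r in report)

    def test_null_size_guard(self):
        with pytest.raises(ValueError):
            ds.build_shift_null(32, 50, 0)

    def test_mismatched_null_rejected(self):
        null = ds.build_shift_null(32, 200, 0)
        with pytest.raises(ValueError, match="tips"):
            ds.scan_shifts(ds.simulate_erm_tree(40, 0), null=null)

    def test_marginal_classification_boundaries(self):
        from divshift.shifts import _classify

        assert _classify(0.049, False) == "significant"
        assert _classify(0.05, False) == "marginal"
        assert _classify(0.05, True) == "significant"
        assert _classify(0.099, False) == "marginal"
        assert _classify(0.10, False) == "nonsignificant"


class TestCountSdr:
    def _report(self, tree, pairs):
        results = []
        for node, p in pairs:
            results.append(
                ds.ShiftResult(
                    branch_id=node.id,
                    clade="x",
                    n_O=1,
                    n_L=1,
                    n_R=1,
                    delta1=1.0,
                    p=p,
                    klass="significant" if p < 0.05 else
                    ("marginal" if p < 0.10 else "nonsignificant"),
                )
            )
        return results

    def test_smallest_containing_clade_wins(self):
        tree = ds.parse_newick("(((a,b),(c,d)),(e,f));")
        inner = next(
            n for n in tree.internal_nodes()
            if tree.clade_tip_labels(n) == frozenset("ab")
        )
        clades = {"A": {"a", "b"}, "B": {"a", "b", "c", "d"}}
        counts = ds.count_sdr(self._report(tree, [(inner, 0.01)]), clades, tree)
        assert counts.loc["A", "significant"] == 1
        assert counts.loc["B", "significant"] == 0

    def test_empty_results_all_zero(self):
        tree = ds.parse_newick("((a,b),(c,d));")
        counts = ds.count_sdr([], {"A": {"a", "b"}}, tree)
        assert (counts.to_numpy() == 0).all()

    def test_non_nested_clades_rejected(self):
        tree = ds.parse_newick("((a,b),(c,d));")
        with pytest.raises(ValueError, match="nesting"):
            ds.count_sdr([], {"A": {"a", "b"}, "B": {"b", "c"}}, tree)

    def test_marginal_counted_separately(self):
        tree = ds.parse_newick("(((a,b),c),(d,e));")
        inner = next(
            n for n in tree.internal_nodes()
            if tree.clade_tip_labels(n) == frozenset("ab")
        )
        counts = ds.count_sdr(
            self._report(tree, [(inner, 0.07)]), {"A": {"a", "b", "c"}}, tree
        )
        assert counts.loc["A", "marginal"] == 1
        assert counts.loc["A", "significant"] == 0
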