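"""Rooted-triplet tests: enumeration, counting, binomial, Holm, gamma,
scan calibration, event collapse."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from introscan.errors import EmptyCountsError, UndefinedStatisticError
from introscan.rttest import (
    RTResult,
    TripletCounts,
    binomial_minor_test,
    collapse_to_events,
    count_topologies,
    enumerate_triplets,
    gamma_from_counts,
    holm_adjust,
    results_from_frame,
    results_to_frame,
    rt_scan,
)
from introscan.simulate import (
    SpeciesNetwork,
    attach_outgroup,
    random_ultrametric_tree,
    simulate_gene_trees,
)
from introscan.treeio import GeneTreeSet, TripletSpec, parse_newick, sister_pairs


def make_counts(major, minor1, minor2, unresolved=0, with_tip="P2"):
    return TripletCounts(
        major=major,
        minor1=minor1,
        minor2=minor2,
        n_unresolved=unresolved,
        n_loci_used=major + minor1 + minor2 + unresolved,
        minor2_with=with_tip,
    )


class TestEnumerate:
    def test_balanced_four(self, balanced4):
        specs = enumerate_triplets(balanced4, "O")
        assert len(specs) == 4  # 2 pairs x 2 remaining ingroups

    def test_caterpillar(self):
        specs = enumerate_triplets(parse_newick("(A,(B,(C,D)));"), "O")
        assert len(specs) == 2

    def test_count_formula_on_random_trees(self):
        from conftest import random_tree_newick

        rng = np.random.default_rng(1)
        for _ in range(5):
            t = parse_newick(random_tree_newick(rng, 30))
            k = len(sister_pairs(t))
            specs = enumerate_triplets(t, "OUT")  # outgroup not in tree's tips
            n_ingroup = 30
            assert len(specs) == k * (n_ingroup - 2)

    def test_no_sister_pairs_warns_empty(self):
        t = parse_newick("(A,B);")  # single cherry contains outgroup B
        with pytest.warns(UserWarning):
            assert enumerate_triplets(t, "B") == []


class TestCounting:
    def test_all_major(self):
        gts = GeneTreeSet(
            [(f"L{i}", parse_newick("(((P1,P2),P3),O);")) for i in range(10)]
        )
        c = count_topologies(gts, TripletSpec("P1", "P2", "P3", "O"))
        assert (c.major, c.minor1, c.minor2, c.n_unresolved) == (10, 0, 0, 0)

    def test_hand_tallied_mix(self):
        newicks = [
            "(((P1,P2),P3),O);",
            "(((P1,P2),P3),O);",
            "(((P1,P2),P3),O);",
            "(((P2,P3),P1),O);",
            "(((P2,P3),P1),O);",
            "(((P1,P3),P2),O);",
            "((P1,P2,P3),O);",
        ]
        gts = GeneTreeSet([(f"L{i}", parse_newick(n)) for i, n in enumerate(newicks)])
        c = count_topologies(gts, TripletSpec("P1", "P2", "P3", "O"))
        assert (c.major, c.minor1, c.minor2, c.n_unresolved) == (3, 1, 2, 1)
        assert c.minor2_with == "P2"  # excess pairing groups P2 with P3

    def test_loci_missing_taxa_excluded(self):
        gts = GeneTreeSet(
            [
                ("L0", parse_newick("(((P1,P2),P3),O);")),
                ("L1", parse_newick("((P1,P2),O);")),  # lacks P3
            ]
        )
        c = count_topologies(gts, TripletSpec("P1", "P2", "P3", "O"))
        assert c.n_loci_used == 1

    def test_zero_usable_loci_raises(self):
        gts = GeneTreeSet([("L0", parse_newick("((A,B),C);"))])
        with pytest.raises(EmptyCountsError):
            count_topologies(gts, TripletSpec("P1", "P2", "P3", "O"))

    def test_counts_invariants_enforced(self):
        with pytest.raises(ValueError):
            TripletCounts(1, 5, 2, 0, 8)  # minor2 < minor1
        with pytest.raises(ValueError):
            TripletCounts(1, 1, 2, 0, 99)  # sum mismatch


class TestBinomial:
    def test_balanced_is_one(self):
        assert binomial_minor_test(make_counts(0, 50, 50)) == 1.0

    def test_degenerate_zero_minors_is_one(self):
        assert binomial_minor_test(make_counts(10, 0, 0)) == 1.0

    def test_30_70_matches_exact_tail_sum(self):
        # oracle: P(X<=30) + P(X>=70), X ~ Bin(100, 1/2)
        oracle = binom.cdf(30, 100, 0.5) + binom.sf(69, 100, 0.5)
        p = binomial_minor_test(make_counts(0, 30, 70))
        assert p == pytest.approx(oracle, rel=1e-12)
        assert p == pytest.approx(7.85e-5, rel=5e-3)


class TestHolm:
    def test_single_p_identity(self):
        assert holm_adjust([0.03]) == pytest.approx([0.03])

    def test_two_p_step_down(self):
        assert holm_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_all_ones(self):
        assert holm_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_never_decreases_and_capped(self):
        rng = np.random.default_rng(2)
        p = rng.random(50)
        adj = holm_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.random(40) ** 3
        ours = holm_adjust(p)
        theirs = multipletests(p, method="holm")[1]
        assert ours == pytest.approx(theirs)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.5])

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_properties_hold_for_arbitrary_inputs(self, p):
        adj = holm_adjust(p)
        assert (adj >= np.asarray(p) - 1e-15).all()
        assert (adj <= 1.0).all()
        # step-down monotonicity: sorting by raw p sorts adjusted p
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()
        # Bonferroni dominates Holm
        assert (adj <= np.minimum(1.0, np.asarray(p) * len(p)) + 1e-15).all()


class TestGamma:
    def test_formula(self):
        assert gamma_from_counts(make_counts(100, 20, 60)) == pytest.approx(40 / 180)

    def test_tie_is_zero(self):
        assert gamma_from_counts(make_counts(10, 7, 7)) == 0.0

    def test_zero_denominator_raises(self):
        with pytest.raises(UndefinedStatisticError):
            gamma_from_counts(make_counts(0, 0, 0, unresolved=4))

    def test_bounded_below_one_with_major(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            major = int(rng.integers(1, 50))
            m1 = int(rng.integers(0, 30))
            m2 = m1 + int(rng.integers(0, 30))
            g = gamma_from_counts(make_counts(major, m1, m2))
            assert 0.0 <= g < 1.0


class TestScan:
    def test_label_swap_leaves_p_and_gamma_magnitude(self):
        newicks = ["(((P1,P2),P3),O);"] * 5 + ["(((P2,P3),P1),O);"] * 4 + [
            "(((P1,P3),P2),O);"
        ]
        gts = GeneTreeSet([(f"L{i}", parse_newick(n)) for i, n in enumerate(newicks)])
        a = count_topologies(gts, TripletSpec("P1", "P2", "P3", "O"))
        b = count_topologies(gts, TripletSpec("P2", "P1", "P3", "O"))
        assert binomial_minor_test(a) == binomial_minor_test(b)
        assert gamma_from_counts(a) == pytest.approx(gamma_from_counts(b))

    def test_empty_gene_set_warns(self, balanced4):
        tree = parse_newick("(((A,B),(C,D)),O);")
        with pytest.warns(UserWarning):
            assert rt_scan(GeneTreeSet([]), tree, "O") == []

    def test_null_calibration_small(self):
        # ILS only: no significant tests at Holm-adjusted 0.001
        ingroup = random_ultrametric_tree(8, seed=20, height=2.0)
        tree = attach_outgroup(ingroup, "OUT", 8.0)
        net = SpeciesNetwork(tree, [])
        n_sig = 0
        for seed in range(5):
            gts = simulate_gene_trees(net, 400, seed=100 + seed)
            res = rt_scan(gts, tree, "OUT")
            n_sig += sum(1 for r in res if r.p_adj < 0.001)
        assert n_sig == 0

    def test_planted_edge_detected_with_positive_gamma(self, planted_10taxon):
        net, edge, gts, _ = planted_10taxon
        res = rt_scan(gts, net.tree, "OUT")
        hits = [
            r
            for r in res
            if r.p_adj < 0.001 and r.spec.p3 == edge.donor and edge.recipient == r.donor_partner
        ]
        assert hits and all(r.gamma > 0 for r in hits)

    def test_results_frame_round_trip(self, planted_10taxon):
        net, _, gts, _ = planted_10taxon
        res = rt_scan(gts, net.tree, "OUT")
        frame = results_to_frame(res)
        back = results_from_frame(frame)
        assert [r.test_id for r in back] == [r.test_id for r in res]
        assert [r.p_adj for r in back] == pytest.approx([r.p_adj for r in res])


class TestCollapse:
    def _result(self, p1, p2, p3, partner, gamma, p_adj=1e-6):
        counts = make_counts(50, 5, 30, with_tip=partner)
        return RTResult(
            TripletSpec(p1, p2, p3, "O"), counts, p_raw=p_adj, p_adj=p_adj, gamma=gamma
        )

    def test_partner_clade_collapses_to_one_event(self):
        tree = parse_newick("(((A,B),(C,D)),X);")
        results = [
            self._result("A", "B", "C", "A", 0.2),
            self._result("A", "B", "D", "A", 0.3),
        ]
        events = collapse_to_events(results, tree)
        assert len(events) == 1
        row = events.iloc[0]
        assert set(row.recipient.split("|")) == {"C", "D"}
        assert row.partner == "A"
        # f-branch-style summary: median over {C,D} of min over {A}
        assert row.gamma == pytest.approx(np.median([0.2, 0.3]))

    def test_disjoint_tests_stay_separate(self):
        tree = parse_newick("(((A,B),(C,D)),((E,F),(G,H)));")
        results = [
            self._result("A", "B", "C", "A", 0.2),
            self._result("E", "F", "G", "F", 0.4),
        ]
        events = collapse_to_events(results, tree)
        assert len(events) == 2

    def test_nonsignificant_excluded(self):
        tree = parse_newick("(((A,B),(C,D)),X);")
        results = [self._result("A", "B", "C", "A", 0.2, p_adj=0.5)]
        assert collapse_to_events(results, tree).empty

    def test_planted_ancestral_edge_collapses_to_stem(self):
        # donor inside a sister pair, recipient = stem of a cherry: the two
        # per-tip tests collapse to one clade-level event
        ingroup = random_ultrametric_tree(8, seed=33, height=2.5)
        tree = attach_outgroup(ingroup, "OUT", 9.0)
        pairs = sister_pairs(ingroup)
        assert len(pairs) >= 2
        from introscan.simulate import HybridEdge

        ages = SpeciesNetwork(tree).ages
        # recipient cherry = youngest pair, donor = member of another pair
        pair_ages = [(float(ages[tree.mrca(a, b)]), (a, b)) for a, b in pairs]
        pair_ages.sort()
        (rc_age, (c1, c2)), (dp_age, (d, e)) = pair_ages[0], pair_ages[-1]
        stem_hi = float(ages[tree.parent[tree.mrca(c1, c2)]])
        tm = rc_age + 0.2 * (min(stem_hi, dp_age) - rc_age)
        edge = HybridEdge(d, f"{c1}|{c2}", tm, 0.35)
        net = SpeciesNetwork(tree, [edge])
        gts = simulate_gene_trees(net, 1200, seed=44)
        res = rt_scan(gts, tree, "OUT")
        events = collapse_to_events(res, tree)
        hit = [
            row
            for row in events.itertuples()
            if {c1, c2} <= set(row.recipient.split("|")) and d in row.partner.split("|")
            or {c1, c2} <= set(row.partner.split("|")) and d in row.recipient.split("|")
        ]
        assert hit, f"no collapsed event for {d} -> {c1}|{c2}:\n{events}"
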