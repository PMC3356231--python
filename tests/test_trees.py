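"""Tree I/O, consensus methods, wildcard pruning, monophyly support."""

import numpy as np
import pytest

from palmdelim import (
    GroupingMap,
    SimSpec,
    TreeSet,
    adams_consensus,
    monophyly_support,
    prune_terminals,
    read_trees,
    simulate_replicate_trees,
    strict_consensus,
    wildcard_scan,
    write_trees,
)
from palmdelim.trees import DuplicateLeafError, TreeFormatError

from conftest import common_nestings, random_tree_set


def clusters_and_supports(tree):
    out = {}

    def walk(node):
        if node.is_leaf:
            return frozenset({node.label})
        cl = frozenset().union(*map(walk, node.children))
        out[cl] = node.support
        return cl

    walk(tree.root)
    return out


def trees_equal(a, b):
    return a.leaf_set == b.leaf_set and clusters_and_supports(
        a
    ) == clusters_and_supports(b)


class TestIO:
    def test_support_on_internal_labels(self):
        ts = read_trees("((A,B)95,C);")
        assert clusters_and_supports(ts[0])[frozenset({"A", "B"})] == 95.0

    def test_auto_scale_proportions(self):
        ts = read_trees("((A,B)0.95,C);")
        assert clusters_and_supports(ts[0])[frozenset({"A", "B"})] == 95.0

    @pytest.mark.parametrize("fmt", ["newick", "nexus"])
    def test_write_read_identity(self, fmt):
        ts = read_trees("((A,B)95,(C,(D,E)80)60);\n((A,(B,C)50),(D,E));")
        back = read_trees(write_trees(ts, fmt), format=fmt)
        assert all(trees_equal(x, y) for x, y in zip(ts, back))

    def test_duplicate_leaf_raises(self):
        with pytest.raises(DuplicateLeafError):
            read_trees("((A,B),(A,C));")

    def test_unbalanced_parentheses_raise(self):
        with pytest.raises(TreeFormatError):
            read_trees("((A,B),C;")


class TestPrune:
    def test_three_leaf_prune(self):
        ts = read_trees("((A,B),C);")
        pruned = prune_terminals(ts, {"C"})
        assert pruned.leaf_set == {"A", "B"}

    def test_empty_drop_is_identity(self):
        ts = read_trees("((A,B),C);")
        assert trees_equal(prune_terminals(ts, set())[0], ts[0])

    def test_suppresses_unifurcation(self):
        ts = read_trees("(R,(A,(B,C)));")
        pruned = prune_terminals(ts, {"R"})
        assert clusters_and_supports(pruned[0]).keys() == {
            frozenset({"A", "B", "C"}),
            frozenset({"B", "C"}),
        }

    def test_dropping_all_leaves_raises(self):
        ts = read_trees("((A,B),C);")
        with pytest.raises(ValueError):
            prune_terminals(ts, {"A", "B", "C"})


class TestStrictConsensus:
    def test_identical_inputs_return_same_tree(self):
        ts = read_trees("((A,B),(C,D));\n((A,B),(C,D));")
        assert trees_equal(strict_consensus(ts), ts[0])

    def test_cluster_intersection_by_hand(self):
        ts = read_trees("((A,B),(C,D));\n(((A,B),C),D);")
        assert set(clusters_and_supports(strict_consensus(ts))) == {
            frozenset({"A", "B"}),
            frozenset({"A", "B", "C", "D"}),
        }

    def test_trio_collapses_to_star(self, trio_trees):
        cons = strict_consensus(trio_trees)
        assert cons.resolution() == 0
        assert len(cons.root.children) == 4


class TestAdamsConsensus:
    def test_identical_inputs_return_same_tree(self):
        ts = read_trees("((A,B),(C,(D,E)));\n((A,B),(C,(D,E)));")
        assert trees_equal(adams_consensus(ts), ts[0])

    def test_trio_retains_nested_pair(self, trio_trees):
        cons = adams_consensus(trio_trees)
        assert set(clusters_and_supports(cons)) == {
            frozenset({"B", "C"}),
            frozenset({"A", "B", "C", "R"}),
        }
        assert len(cons.root.children) == 3  # blocks {A}, {R}, {B,C}

    def test_conflicting_pair_gives_star(self):
        ts = read_trees("((A,B),C);\n((A,C),B);")
        assert adams_consensus(ts).resolution() == 0


class TestConsensusProperties:
    """Randomized verification against independent cluster/nesting oracles."""

    def test_strict_is_cluster_intersection(self):
        rng = np.random.default_rng(1)
        for _ in range(40):
            ts = random_tree_set(rng, int(rng.integers(3, 8)), int(rng.integers(1, 4)))
            expected = frozenset.intersection(
                *(frozenset(t.clusters()) for t in ts)
            )
            assert frozenset(strict_consensus(ts).clusters()) == expected

    def test_adams_preserves_common_nestings(self):
        """Soundness over all subset pairs; exactness relative to its clusters."""
        rng = np.random.default_rng(2)
        for _ in range(30):
            ts = random_tree_set(rng, int(rng.integers(3, 8)), int(rng.integers(2, 4)))
            cons = adams_consensus(ts)
            common = common_nestings(list(ts))
            for inner, outer in common:
                assert cons.nests_in(inner, outer)
            adams_clusters = cons.clusters()
            for inner, outer in common_nestings([cons]):
                if outer in adams_clusters:
                    assert (inner, outer) in common

    def test_consensus_invariant_to_tree_order(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            ts = random_tree_set(rng, 6, 3)
            rev = TreeSet(list(ts)[::-1])
            assert trees_equal(strict_consensus(ts), strict_consensus(rev))
            assert trees_equal(adams_consensus(ts), adams_consensus(rev))

    def test_single_tree_consensus_is_identity(self):
        rng = np.random.default_rng(4)
        ts = random_tree_set(rng, 7, 1)
        assert trees_equal(adams_consensus(ts), ts[0])
        assert trees_equal(strict_consensus(ts), ts[0])


class TestWildcardScan:
    def test_trio_removes_the_rogue(self, trio_trees):
        res = wildcard_scan(trio_trees)
        assert res.removed == ["R"]
        assert res.resolution_trajectory == [0, 1]

    def test_identical_trees_remove_nothing(self):
        ts = read_trees("((A,B),(C,D));\n((A,B),(C,D));")
        res = wildcard_scan(ts)
        assert res.removed == []

    def test_protected_rogue_is_blocked(self, trio_trees):
        res = wildcard_scan(trio_trees, protected={"R"})
        assert res.removed == []
        assert res.blocked_candidate == ("R", 1)

    def test_trajectory_non_decreasing(self):
        rng = np.random.default_rng(5)
        ts = random_tree_set(rng, 7, 3)
        res = wildcard_scan(ts)
        traj = res.resolution_trajectory
        assert traj == sorted(traj)

    def test_planted_rogue_is_found_exactly(self):
        spec = SimSpec(seed=7, n_species=3, n_rogues=1, n_tree_replicates=30)
        ts, truth = simulate_replicate_trees(spec)
        res = wildcard_scan(ts)
        assert res.removed == truth.rogue_labels
        grouping = GroupingMap(
            {t: sp for t, sp in truth.species_of_terminal.items()},
            {sp: sp for sp in set(truth.species_of_terminal.values())},
        )
        for rec in monophyly_support(res.final_trees, grouping):
            assert rec.support == 100.0


class TestMonophylySupport:
    grouping = GroupingMap(
        {"A": "pA", "B": "pBC", "C": "pBC", "R": "pR"},
        {"pA": "one", "pBC": "two", "pR": "three"},
    )

    def test_fraction_of_replicates(self, trio_trees):
        recs = {r.species: r for r in monophyly_support(trio_trees, self.grouping)}
        assert recs["two"].support == pytest.approx(200 / 3)
        assert recs["two"].status == "monophyletic"  # cluster in the first tree

    def test_entire_leaf_set_is_trivially_supported(self, trio_trees):
        g = GroupingMap(
            {l: "p" for l in "ABCR"}, {"p": "all"}
        )
        (rec,) = monophyly_support(trio_trees, g)
        assert rec.support == 100.0

    def test_singleton_not_assessed(self, trio_trees):
        recs = {r.species: r for r in monophyly_support(trio_trees, self.grouping)}
        assert recs["one"].status == "not-assessed"
        assert recs["one"].support is None

    def test_unsampled_species_not_assessed(self, trio_trees):
        g = GroupingMap(
            {"A": "pA", "B": "pBC", "C": "pBC", "R": "pR", "zz": "pz"},
            {"pA": "one", "pBC": "two", "pR": "three", "pz": "ghost"},
        )
        recs = {r.species: r for r in monophyly_support(trio_trees, g)}
        assert recs["ghost"].status == "not-assessed"

    def test_perfect_replicates_give_full_support(self):
        spec = SimSpec(seed=9, n_species=3, n_tree_replicates=20)
        ts, truth = simulate_replicate_trees(spec)
        g = GroupingMap(
            {t: sp for t, sp in truth.species_of_terminal.items()},
            {sp: sp for sp in set(truth.species_of_terminal.values())},
        )
        for rec in monophyly_support(ts, g):
            assert rec.status == "monophyletic"
            assert rec.support == 100.0
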