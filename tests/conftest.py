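import itertools

import numpy as np
import pytest

from palmdelim.paa import PopulationProfile
from palmdelim.trees import Node, Tree, TreeSet


@pytest.fixture
def trio_trees():
    """Three rooted trees in which R wanders across positions."""
    from palmdelim import read_trees

    return read_trees("(R,(A,(B,C)));\n(A,(R,(B,C)));\n(A,(B,(R,C)));")


@pytest.fixture
def evanno_example():
    """Replicate LnP table with a knee at K=2."""
    from palmdelim import LnPTable

    return LnPTable(
        {
            1: [-1010, -1000, -990],
            2: [-810, -800, -790],
            3: [-795, -790, -785],
            4: [-790, -785, -780],
        }
    )


def make_profile(unit, state_sets, char_ids=None, members=None):
    """Shorthand PopulationProfile over an explicit state-set list."""
    char_ids = char_ids or [f"c{i + 1}" for i in range(len(state_sets))]
    states = {c: frozenset(s) for c, s in zip(char_ids, state_sets)}
    return PopulationProfile(unit, char_ids, states, members or [f"{unit}_t1"])


def random_profiles(
    rng, n_units=None, n_chars=None, alphabet=("A", "B", "C"),
    allow_missing_only=False,
):
    """Random small PAA instance.

    With ``allow_missing_only`` an occasional empty state set models a unit
    wholly missing at a character.  Merging such a unit can create new
    diagnosability, so the fixed point is order-dependent in general; the
    default instances keep every profile observed, the condition under which
    the fixed point is provably unique.
    """
    n_units = n_units or rng.integers(2, 7)
    n_chars = n_chars or rng.integers(1, 5)
    profiles = []
    for u in range(n_units):
        sets = []
        for _ in range(n_chars):
            if allow_missing_only and rng.random() < 0.15:
                sets.append(frozenset())
            else:
                k = rng.integers(1, len(alphabet) + 1)
                sets.append(frozenset(rng.choice(alphabet, size=k, replace=False)))
        profiles.append(make_profile(f"U{u + 1}", sets))
    return profiles


def random_rooted_tree(rng, leaves):
    """Random rooted tree, polytomies allowed, over the given leaf labels."""
    leaves = list(leaves)
    if len(leaves) == 1:
        return Node(label=leaves[0])
    n_blocks = int(rng.integers(2, len(leaves) + 1))
    order = list(rng.permutation(leaves))
    cuts = sorted(rng.choice(range(1, len(leaves)), size=n_blocks - 1, replace=False))
    blocks, start = [], 0
    for cut in list(cuts) + [len(leaves)]:
        blocks.append(order[start:cut])
        start = cut
    return Node(children=[random_rooted_tree(rng, b) for b in blocks])


def random_tree_set(rng, n_leaves, n_trees):
    labels = [f"L{i + 1}" for i in range(n_leaves)]
    return TreeSet([Tree(random_rooted_tree(rng, labels)) for _ in range(n_trees)])


def common_nestings(trees, leaf_subsets=None):
    """All (inner, outer) pairs, |inner|>=2, nested in every tree."""
    leaves = sorted(trees[0].leaf_set)
    out = set()
    for r_out in range(2, len(leaves) + 1):
        for outer in itertools.combinations(leaves, r_out):
            outer_f = frozenset(outer)
            for r_in in range(2, r_out + 1):
                for inner in itertools.combinations(outer, r_in):
                    inner_f = frozenset(inner)
                    if inner_f == outer_f:
                        continue
                    if all(t.nests_in(inner_f, outer_f) for t in trees):
                        out.add((inner_f, outer_f))
    return out
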