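"""Synthetic inputs with known truth for every pipeline stage.

Three generators emulate the shapes of the study's data without downloads:
multistate character matrices with planted mutually exclusive state
differences between species pairs (plus polymorphism and missing-data
noise), replicate tree sets with controllable per-species monophyly and
rogue terminals regrafted independently per replicate, and admixture
replicate Q matrices with Dirichlet noise and random cluster-label
permutations alongside an LnP(K) series whose curvature knees at the true K.

All randomness flows from one master seed; each generator derives its own
independent stream by a fixed offset so the three outputs are individually
reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .clusters import LnPTable, QReplicateSet
from .matrices import (
    MICROSATELLITE,
    MISSING,
    MORPHOLOGICAL,
    SEQUENCE,
    Character,
    CharacterMatrix,
    GroupingMap,
)
from .trees import Node, Tree, TreeSet, _leafset_of

__all__ = ["SimSpec", "SyntheticTruth", "simulate_character_matrix",
           "simulate_replicate_trees", "simulate_structure_run"]

_MATRIX_STREAM, _TREE_STREAM, _STRUCTURE_STREAM = 1, 2, 3


@dataclass
class SimSpec:
    """Generator configuration; the defaults are the study-like conditions.

    Sampling defaults follow the study's reported design: a handful of
    populations per species with a few individuals each, five
    microsatellite-style loci, ten morphology-style characters, ten admixture
    replicates per K.  Diagnostic planting, noise rates and the LnP knee are
    the package's own minimal model of those data shapes (see the methods
    note).
    """

    seed: int = 0
    # character matrix
    n_species: int = 5
    pops_per_species: int = 2
    terminals_per_pop: int = 3
    n_sequence_chars: int = 60
    n_microsat_chars: int = 5
    n_morph_chars: int = 10
    diag_per_pair: int = 2
    polymorphism_rate: float = 0.1
    missing_rate: float = 0.05
    # replicate trees
    n_tree_replicates: int = 100
    p_monophyly: float = 1.0
    n_rogues: int = 0
    # admixture run
    true_k: int = None  # defaults to n_species
    k_min: int = 1
    k_max: int = 10
    replicates_per_k: int = 10
    admixture_concentration: float = 50.0  # Dirichlet weight on own cluster
    q_noise_concentration: float = 200.0  # replicate perturbation sharpness
    lnp_base: float = -3000.0
    lnp_slope_pre: float = 200.0  # LnP slope below the true K
    lnp_slope_post: float = 20.0  # LnP slope above the true K
    lnp_noise_sd: float = 10.0

    def __post_init__(self):
        for name in ("polymorphism_rate", "missing_rate", "p_monophyly"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "n_species", "pops_per_species", "terminals_per_pop",
            "n_tree_replicates", "replicates_per_k",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.true_k is None:
            self.true_k = self.n_species
        if not (self.k_min <= self.true_k <= self.k_max):
            raise ValueError("true K outside the requested K range")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])

    def with_(self, **kw) -> "SimSpec":
        return replace(self, **kw)


@dataclass
class SyntheticTruth:
    species_of_terminal: dict = field(default_factory=dict)
    diagnostic_map: dict = field(default_factory=dict)  # (sp_i, sp_j) -> char ids
    rogue_labels: list = field(default_factory=list)
    true_k: int = None
    true_q: np.ndarray = None
    individuals: list = field(default_factory=list)


def _terminal_names(spec: SimSpec):
    """(terminal, population, species) triples in deterministic order."""
    out = []
    for s in range(spec.n_species):
        sp = f"species{s + 1}"
        for p in range(spec.pops_per_species):
            pop = f"{sp}_pop{p + 1}"
            for i in range(spec.terminals_per_pop):
                out.append((f"{sp}_p{p + 1}_t{i + 1}", pop, sp))
    return out


def _grouping(spec: SimSpec) -> GroupingMap:
    triples = _terminal_names(spec)
    return GroupingMap(
        {t: pop for t, pop, _ in triples},
        {pop: sp for _, pop, sp in triples},
    )


# ---------------------------------------------------------------------------
# Character matrices


def simulate_character_matrix(spec: SimSpec):
    """Matrix with planted pairwise-disjoint states plus noise.

    For every unordered species pair, ``diag_per_pair`` sequence characters
    carry state "0" fixed in the first species and "1" in the second, all
    other species polymorphic {0, 1}: the character is diagnostic for exactly
    that pair.  Remaining characters are noise: states drawn per terminal,
    with the first terminal of every species forced to the shared state "0"
    so noise characters can never separate species by themselves.
    Polymorphism makes a noise cell two-state; missing replaces cells at the
    given rate, but the first terminal of each species in a diagnostic pair
    keeps its planted cell so the planted contrast survives any rate.

    Returns ``(CharacterMatrix, GroupingMap, SyntheticTruth)``.
    """
    rng = spec.rng(_MATRIX_STREAM)
    triples = _terminal_names(spec)
    grouping = _grouping(spec)
    terminals = [t for t, _, _ in triples]
    species = [f"species{s + 1}" for s in range(spec.n_species)]
    first_terminal = {}
    for t, _, sp in triples:
        first_terminal.setdefault(sp, t)

    pairs = list(itertools.combinations(species, 2))
    n_diag = spec.diag_per_pair * len(pairs)
    if n_diag > spec.n_sequence_chars:
        raise ValueError(
            f"infeasible: {n_diag} diagnostic characters requested but only "
            f"{spec.n_sequence_chars} sequence characters available"
        )

    chars: list = []
    cells: dict = {}
    truth = SyntheticTruth(
        species_of_terminal={t: sp for t, _, sp in triples},
        true_k=spec.true_k,
    )
    alpha01 = frozenset({"0", "1"})

    def add_char(cid, klass, alphabet):
        chars.append(Character(cid, klass, frozenset(alphabet)))

    # planted diagnostics
    protected = set()  # (terminal, char id) cells immune to missing
    for (sp_a, sp_b) in pairs:
        ids = []
        for d in range(spec.diag_per_pair):
            cid = f"diag_{sp_a}_{sp_b}_{d + 1}"
            ids.append(cid)
            add_char(cid, SEQUENCE, alpha01)
            for t, _, sp in triples:
                if sp == sp_a:
                    cells[(t, cid)] = frozenset({"0"})
                elif sp == sp_b:
                    cells[(t, cid)] = frozenset({"1"})
                else:
                    cells[(t, cid)] = alpha01
            protected.add((first_terminal[sp_a], cid))
            protected.add((first_terminal[sp_b], cid))
        truth.diagnostic_map[(sp_a, sp_b)] = ids

    # noise characters per class
    def add_noise(prefix, klass, n, states):
        for j in range(n):
            cid = f"{prefix}{j + 1}"
            add_char(cid, klass, frozenset(states) | {"0"})
            for t, _, sp in triples:
                if t == first_terminal[sp]:
                    st = {"0"}
                else:
                    st = {str(rng.choice(states))}
                if rng.random() < spec.polymorphism_rate:
                    st = st | {str(rng.choice(states))}
                cells[(t, cid)] = frozenset(st)

    add_noise("seq", SEQUENCE, spec.n_sequence_chars - n_diag, ["0", "1"])
    add_noise("msat", MICROSATELLITE, spec.n_microsat_chars,
              ["150", "152", "154", "0"])
    add_noise("morph", MORPHOLOGICAL, spec.n_morph_chars, ["0", "1", "2"])

    # missing-data mask
    if spec.missing_rate > 0:
        for t, _, _ in triples:
            for c in chars:
                key = (t, c.id)
                if key in protected:
                    continue
                if rng.random() < spec.missing_rate:
                    cells[key] = MISSING

    return CharacterMatrix(terminals, chars, cells), grouping, truth


# ---------------------------------------------------------------------------
# Replicate trees


def _species_base_tree(spec: SimSpec) -> Node:
    triples = _terminal_names(spec)
    by_species: dict = {}
    for t, _, sp in triples:
        by_species.setdefault(sp, []).append(t)
    clades = []
    for sp in by_species:
        leaves = [Node(label=t) for t in by_species[sp]]
        clades.append(leaves[0] if len(leaves) == 1 else Node(children=leaves))
    # ladderized backbone over species clades
    node = clades[0]
    for clade in clades[1:]:
        node = Node(children=[node, clade])
    return node


def _all_nodes(node: Node):
    stack = [node]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


def _detach_leaf(root: Node, label: str) -> Node:
    """Remove the named leaf in place, suppressing the unifurcation."""

    def walk(node):
        for i, c in enumerate(node.children):
            if c.is_leaf and c.label == label:
                node.children.pop(i)
                return True
            if not c.is_leaf and walk(c):
                if len(c.children) == 1:
                    node.children[node.children.index(c)] = c.children[0]
                return True
        return False

    walk(root)
    if len(root.children) == 1:
        root = root.children[0]
    return root


def _attach_leaf(root: Node, leaf: Node, rng, avoid: frozenset = frozenset()) -> Node:
    """Graft ``leaf`` onto a uniformly chosen node (as a new sibling).

    ``avoid`` excludes attachment points that would recreate a clade over
    ``avoid | {leaf}``: targets whose leaf set meets ``avoid`` without
    strictly containing it.  Used when regrafting a species member so that a
    regraft really breaks the species' monophyly.
    """
    targets = []
    for n in _all_nodes(root):
        if avoid:
            ls = _leafset_of(n)
            inter = ls & avoid
            if inter and not (ls > avoid):
                continue
        targets.append(n)
    target = targets[rng.integers(len(targets))]
    if target is root:
        return Node(children=[root, leaf])

    def walk(node):
        for i, c in enumerate(node.children):
            if c is target:
                node.children[i] = Node(children=[c, leaf])
                return True
            if walk(c):
                return True
        return False

    walk(root)
    return root


def simulate_replicate_trees(spec: SimSpec):
    """Replicate trees with controllable monophyly and rogue terminals.

    A fixed base tree keeps every species monophyletic.  Per replicate, each
    species stays intact with probability ``p_monophyly``; otherwise one of
    its members is regrafted to a random position.  Each rogue terminal is
    regrafted to an independently random position in every replicate.

    Returns ``(TreeSet, SyntheticTruth)``; the grouping for downstream
    monophyly assessment is the one from :func:`simulate_character_matrix`.
    """
    n_leaves = spec.n_species * spec.pops_per_species * spec.terminals_per_pop
    if spec.n_rogues >= max(1, n_leaves):
        raise ValueError("rogue count must be smaller than the leaf count")
    rng = spec.rng(_TREE_STREAM)
    base = _species_base_tree(spec)
    rogues = [f"rogue{i + 1}" for i in range(spec.n_rogues)]
    triples = _terminal_names(spec)
    by_species: dict = {}
    for t, _, sp in triples:
        by_species.setdefault(sp, []).append(t)
    trees = []
    for _ in range(spec.n_tree_replicates):
        root = base.copy()
        for sp, members in by_species.items():
            if len(members) < 2:
                continue
            if rng.random() >= spec.p_monophyly:
                wanderer = members[rng.integers(len(members))]
                rest = frozenset(members) - {wanderer}
                root = _detach_leaf(root, wanderer)
                root = _attach_leaf(root, Node(label=wanderer), rng, avoid=rest)
        for label in rogues:
            root = _attach_leaf(root, Node(label=label), rng)
        trees.append(Tree(root))
    truth = SyntheticTruth(
        species_of_terminal={t: sp for t, _, sp in triples},
        rogue_labels=rogues,
    )
    return TreeSet(trees), truth


# ---------------------------------------------------------------------------
# Admixture replicates and LnP(K)


def simulate_structure_run(spec: SimSpec):
    """Q replicates per K plus an LnP(K) table kneed at the true K.

    Each individual's true membership row is a Dirichlet draw concentrated
    on its species' own cluster (weight ``admixture_concentration`` on the
    own cluster, 1 elsewhere; large values give crisp assignment, 1 gives
    uniform admixture).  A replicate is a Dirichlet perturbation of the true
    row (sharpness ``q_noise_concentration``) followed by a random cluster-
    label permutation, emulating label switching across runs.  Mean LnP(K)
    is piecewise linear with slopes ``lnp_slope_pre`` / ``lnp_slope_post``
    meeting at the true K; replicates add Gaussian noise.

    Returns ``(dict K -> QReplicateSet, LnPTable, SyntheticTruth)``.
    """
    rng = spec.rng(_STRUCTURE_STREAM)
    triples = _terminal_names(spec)
    individuals = [t for t, _, _ in triples]
    species = [f"species{s + 1}" for s in range(spec.n_species)]
    own_cluster = {sp: i for i, sp in enumerate(species)}

    q_by_k: dict = {}
    truth = SyntheticTruth(
        species_of_terminal={t: sp for t, _, sp in triples},
        true_k=spec.true_k,
        individuals=individuals,
    )
    for k in range(spec.k_min, spec.k_max + 1):
        if k == 1:
            true_q = np.ones((len(individuals), 1))
            reps = [true_q.copy() for _ in range(spec.replicates_per_k)]
            q_by_k[k] = QReplicateSet(individuals, reps)
            if k == spec.true_k:
                truth.true_q = true_q
            continue
        alpha = np.ones((len(individuals), k))
        for i, (t, _, sp) in enumerate(triples):
            alpha[i, own_cluster[sp] % k] = spec.admixture_concentration
        true_q = np.vstack([rng.dirichlet(a) for a in alpha])
        reps = []
        for _ in range(spec.replicates_per_k):
            noisy = np.vstack([
                rng.dirichlet(np.maximum(row * spec.q_noise_concentration, 1e-3))
                for row in true_q
            ])
            perm = rng.permutation(k)
            reps.append(noisy[:, perm])
        q_by_k[k] = QReplicateSet(individuals, reps)
        if k == spec.true_k:
            truth.true_q = true_q

    lnp: dict = {}
    for k in range(spec.k_min, spec.k_max + 1):
        if k <= spec.true_k:
            mean = spec.lnp_base + spec.lnp_slope_pre * (k - spec.k_min)
        else:
            mean = (
                spec.lnp_base
                + spec.lnp_slope_pre * (spec.true_k - spec.k_min)
                + spec.lnp_slope_post * (k - spec.true_k)
            )
        lnp[k] = list(mean + spec.lnp_noise_sd * rng.standard_normal(
            spec.replicates_per_k
        ))
    return q_by_k, LnPTable(lnp), truth
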