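"""Rooted-tree operations for the monophyly criterion.

Covers tree I/O (Newick/NEXUS through dendropy), strict and Adams consensus,
iterative wildcard (rogue) terminal pruning, and per-species monophyly and
replicate support.

Trees are treated as rooted as read.  The strict consensus contains exactly
the rooted clusters common to all input trees; the Adams consensus is built
by the standard product-partition recursion: partition the leaves by the
common refinement of the trees' root-child leaf-partitions, restrict each
tree to each block, and recurse.  Adams consensus retains nesting structure
even when a few terminals wander across replicates, which is what makes it
the tool of choice for spotting such wildcards: pruning a wandering terminal
restores resolution in the strict consensus.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import dendropy

from .matrices import GroupingMap

__all__ = [
    "Node",
    "Tree",
    "TreeSet",
    "TreeFormatError",
    "DuplicateLeafError",
    "MonophylyRecord",
    "WildcardRound",
    "WildcardScanResult",
    "read_trees",
    "write_trees",
    "prune_terminals",
    "reroot_on_outgroup",
    "strict_consensus",
    "adams_consensus",
    "wildcard_scan",
    "monophyly_support",
]


class TreeFormatError(ValueError):
    """Unparseable tree text (unbalanced parentheses etc.)."""


class DuplicateLeafError(TreeFormatError):
    """A leaf label appears more than once in a tree."""


class Node:
    """Rooted tree node; a leaf iff it has no children."""

    __slots__ = ("label", "support", "length", "children")

    def __init__(self, label=None, support=None, length=None, children=None):
        self.label = label
        self.support = support
        self.length = length
        self.children = children or []

    @property
    def is_leaf(self):
        return not self.children

    def copy(self) -> "Node":
        return Node(
            self.label,
            self.support,
            self.length,
            [c.copy() for c in self.children],
        )


class Tree:
    """A rooted, leaf-labelled tree with optional internal support values."""

    def __init__(self, root: Node):
        self.root = root
        labels = self.leaf_labels()
        if len(labels) != len(set(labels)):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise DuplicateLeafError(f"duplicate leaf label(s): {dup}")
        for node in self.preorder():
            if not node.is_leaf and len(node.children) < 2:
                raise TreeFormatError("internal node with fewer than 2 children")

    # -- traversal -----------------------------------------------------
    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self):
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self):
        return [n.label for n in self.leaves()]

    @property
    def leaf_set(self) -> frozenset:
        return frozenset(self.leaf_labels())

    # -- clusters ------------------------------------------------------
    def clusters(self) -> set:
        """Rooted clusters: leaf sets of all internal nodes, root included."""

        out = set()

        def walk(node) -> frozenset:
            if node.is_leaf:
                return frozenset({node.label})
            cl = frozenset().union(*(walk(c) for c in node.children))
            out.add(cl)
            return cl

        walk(self.root)
        return out

    def is_cluster(self, labels: frozenset) -> bool:
        return labels in self.clusters() or (
            len(labels) == 1 and labels <= self.leaf_set
        )

    def resolution(self) -> int:
        """Count of non-root internal edges (polytomies allowed)."""
        return sum(
            1
            for n in self.preorder()
            if not n.is_leaf and n is not self.root
        )

    def normalized_resolution(self) -> float:
        n = len(self.leaf_labels())
        return self.resolution() / (n - 2) if n > 2 else 0.0

    def mrca(self, labels) -> Node:
        """Deepest node whose subtended leaf set contains all of ``labels``."""
        labels = frozenset(labels)
        if not labels:
            raise ValueError("empty label set")
        if not labels <= self.leaf_set:
            raise ValueError("labels not all present in tree")
        node = self.root
        while True:
            descend = None
            for c in node.children:
                if labels <= _leafset_of(c):
                    descend = c
                    break
            if descend is None:
                return node
            node = descend

    def nests_in(self, inner, outer) -> bool:
        """True iff mrca(inner) is a proper descendant of mrca(outer)."""
        inner, outer = frozenset(inner), frozenset(outer)
        if not inner <= outer:
            raise ValueError("inner set must be a subset of outer set")
        # mrca(inner) always lies within the subtree of mrca(outer)
        return self.mrca(inner) is not self.mrca(outer)

    # -- editing -------------------------------------------------------
    def copy(self) -> "Tree":
        return Tree(self.root.copy())

    def pruned(self, drop) -> "Tree":
        drop = set(drop)
        if self.leaf_set <= drop:
            raise ValueError("cannot drop every leaf")

        def walk(node):
            if node.is_leaf:
                return None if node.label in drop else node
            kept = [w for w in (walk(c) for c in node.children) if w is not None]
            if not kept:
                return None
            if len(kept) == 1:
                # suppress the unifurcation; keep the child's identity
                child = kept[0]
                if node.length is not None and child.length is not None:
                    child.length += node.length
                return child
            node.children = kept
            return node

        root = walk(self.root.copy())
        while root is not None and len(root.children) == 1:
            root = root.children[0]
        return Tree(root)

    def restricted(self, keep) -> "Tree":
        return self.pruned(self.leaf_set - frozenset(keep))

    # -- serialization -------------------------------------------------
    def newick(self, support_scale: str = "percent") -> str:
        def fmt(node) -> str:
            if node.is_leaf:
                s = _quote(node.label)
            else:
                inner = ",".join(fmt(c) for c in node.children)
                lab = ""
                if node.support is not None:
                    v = node.support
                    if support_scale == "proportion":
                        v = v / 100.0
                    lab = _fmt_num(v)
                s = f"({inner}){lab}"
            if node.length is not None:
                s += f":{_fmt_num(node.length)}"
            return s

        return fmt(self.root) + ";"

    def __repr__(self):
        return f"<Tree {len(self.leaf_labels())} leaves: {self.newick()}>"


def _quote(label: str) -> str:
    if any(ch in label for ch in " (),:;'[]"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _fmt_num(v) -> str:
    if float(v) == int(v):
        return str(int(v))
    return repr(float(v))


@dataclass
class TreeSet:
    """An ordered list of rooted trees over one shared leaf set."""

    trees: list

    def __post_init__(self):
        if not self.trees:
            raise ValueError("empty tree set")
        ls = self.trees[0].leaf_set
        for t in self.trees[1:]:
            if t.leaf_set != ls:
                raise ValueError("trees have mismatched leaf sets")

    @property
    def leaf_set(self) -> frozenset:
        return self.trees[0].leaf_set

    def __len__(self):
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i):
        return self.trees[i]


# ---------------------------------------------------------------------------
# I/O via dendropy


def _from_dendropy(dtree: dendropy.Tree) -> Tree:
    def conv(dnode) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else dnode.label
            return Node(label=label, length=dnode.edge.length)
        support = None
        raw = dnode.label
        if raw is None and dnode.taxon is not None:
            raw = dnode.taxon.label
        if raw is not None:
            try:
                support = float(raw)
            except ValueError:
                support = None
        return Node(
            support=support,
            length=dnode.edge.length,
            children=[conv(c) for c in dnode.child_nodes()],
        )

    return Tree(conv(dtree.seed_node))


def read_trees(source, format: str = "newick", support_scale: str = "auto") -> TreeSet:
    """Read rooted trees; internal node labels become support values.

    ``support_scale``: ``'percent'`` keeps values as read, ``'proportion'``
    multiplies by 100, ``'auto'`` treats values as proportions when every
    support is <= 1.  Supports are held internally on the 0-100 scale.
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"unknown tree format {format!r}")
    if isinstance(source, (str, os.PathLike)) and os.path.exists(source):
        with open(source) as fh:
            text = fh.read()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    try:
        dlist = dendropy.TreeList.get(
            data=text,
            schema=format,
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        msg = str(exc)
        if "duplicate" in msg.lower() or "multiple occurrences" in msg.lower():
            raise DuplicateLeafError(msg) from exc
        raise TreeFormatError(f"cannot parse {format} trees: {exc}") from exc
    if not dlist:
        raise TreeFormatError("no trees found in source")
    trees = [_from_dendropy(dt) for dt in dlist]
    supports = [
        n.support
        for t in trees
        for n in t.preorder()
        if n.support is not None
    ]
    scale = support_scale
    if scale == "auto":
        scale = "proportion" if supports and max(supports) <= 1.0 else "percent"
    if scale == "proportion":
        for t in trees:
            for n in t.preorder():
                if n.support is not None:
                    n.support *= 100.0
    elif scale != "percent":
        raise ValueError(f"unknown support scale {scale!r}")
    return TreeSet(trees)


def write_trees(trees: TreeSet, format: str = "newick", support_scale: str = "percent") -> str:
    """Serialize a tree set; round-trips topology, labels, and support."""
    newicks = [t.newick(support_scale=support_scale) for t in trees]
    if format == "newick":
        return "\n".join(newicks) + "\n"
    if format == "nexus":
        lines = ["#NEXUS", "BEGIN TREES;"]
        for i, nwk in enumerate(newicks, 1):
            lines.append(f"    TREE tree{i} = [&R] {nwk}")
        lines += ["END;", ""]
        return "\n".join(lines)
    raise ValueError(f"unknown tree format {format!r}")


# ---------------------------------------------------------------------------
# Editing operations


def prune_terminals(trees: TreeSet, drop) -> TreeSet:
    """Remove leaves from every tree, suppressing unifurcations."""
    drop = frozenset(drop)
    extra = drop - trees.leaf_set
    if extra:
        raise ValueError(f"labels not in the tree set: {sorted(extra)}")
    if drop >= trees.leaf_set:
        raise ValueError("cannot drop all leaves")
    if not drop:
        return TreeSet([t.copy() for t in trees])
    return TreeSet([t.pruned(drop) for t in trees])


def reroot_on_outgroup(trees: TreeSet, outgroup) -> TreeSet:
    """Reroot each tree so the outgroup's mrca subtends one side of the root.

    Precedes monophyly assessment when the input trees were stored with an
    arbitrary rooting; monophyly statements are about rooted clades with
    sampled outgroups.
    """
    outgroup = frozenset(outgroup)
    if not outgroup <= trees.leaf_set:
        raise ValueError("outgroup labels not in tree set")
    rerooted = []
    for t in trees:
        dt = dendropy.Tree.get(
            data=t.newick(), schema="newick", rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
        taxa = [
            leaf.taxon for leaf in dt.leaf_node_iter() if leaf.taxon.label in outgroup
        ]
        mrca = dt.mrca(taxa=taxa)
        if mrca is not dt.seed_node:
            dt.reroot_at_edge(mrca.edge, update_bipartitions=False)
        rerooted.append(_from_dendropy(dt))
    return TreeSet(rerooted)


# ---------------------------------------------------------------------------
# Consensus


def _tree_from_clusters(leaf_set: frozenset, clusters: set) -> Tree:
    """Build the rooted tree whose internal nodes are a laminar cluster family."""
    clusters = set(clusters) | {leaf_set}
    nodes = {cl: Node() for cl in clusters}
    for leaf in leaf_set:
        nodes[frozenset({leaf})] = Node(label=leaf)
    by_size = sorted(clusters, key=len)
    parent_of = {}
    all_sets = by_size + [frozenset({l}) for l in leaf_set]
    for child in all_sets:
        if child == leaf_set:
            continue
        best = None
        for cand in by_size:
            if child < cand and (best is None or len(cand) < len(best)):
                best = cand
        parent_of[child] = best
    for child, parent in parent_of.items():
        nodes[parent].children.append(nodes[child])
    for node in nodes.values():
        node.children.sort(key=lambda n: min(_leafset_of(n)))
    return Tree(nodes[leaf_set])


def _leafset_of(node: Node) -> frozenset:
    if node.is_leaf:
        return frozenset({node.label})
    return frozenset().union(*(_leafset_of(c) for c in node.children))


def strict_consensus(trees: TreeSet) -> Tree:
    """The rooted tree containing exactly the clusters common to all inputs."""
    common = set.intersection(*(t.clusters() for t in trees))
    return _tree_from_clusters(trees.leaf_set, common)


def adams_consensus(trees: TreeSet) -> Tree:
    """Adams consensus by recursive product of root-child leaf partitions."""

    def product_blocks(tree_list, leaves: frozenset) -> list:
        # signature of a leaf = tuple of block indices across trees
        sig = {leaf: [] for leaf in leaves}
        for t in tree_list:
            root = t.root
            for idx, child in enumerate(root.children):
                for leaf in _leafset_of(child):
                    sig[leaf].append(idx)
        blocks: dict = {}
        for leaf, s in sig.items():
            blocks.setdefault(tuple(s), set()).add(leaf)
        return [frozenset(b) for b in blocks.values()]

    def recurse(tree_list) -> Node:
        leaves = tree_list[0].leaf_set
        if len(leaves) == 1:
            return Node(label=next(iter(leaves)))
        blocks = product_blocks(tree_list, leaves)
        if len(blocks) == 1:
            # cannot happen for well-formed rooted trees (root has >=2
            # children, so each tree's own partition is non-trivial)
            raise RuntimeError("degenerate product partition")
        children = []
        for block in sorted(blocks, key=min):
            if len(block) == 1:
                children.append(Node(label=next(iter(block))))
            else:
                children.append(recurse([t.restricted(block) for t in tree_list]))
        return Node(children=children)

    return Tree(recurse(list(trees)))


# ---------------------------------------------------------------------------
# Wildcard scan


@dataclass
class WildcardRound:
    removed: str
    gain: int
    resolution: int  # strict-consensus resolution after the removal
    strict: Tree
    adams: Tree


@dataclass
class WildcardScanResult:
    removed: list  # labels in removal order
    rounds: list  # WildcardRound per removal
    initial_resolution: int
    initial_strict: Tree
    initial_adams: Tree
    blocked_candidate: tuple = None  # (label, gain) best candidate vetoed
    final_trees: TreeSet = None

    @property
    def resolution_trajectory(self) -> list:
        return [self.initial_resolution] + [r.resolution for r in self.rounds]


def wildcard_scan(
    trees: TreeSet,
    protected=frozenset(),
    min_gain: int = 1,
    max_rounds: int = None,
) -> WildcardScanResult:
    """Greedy wildcard-terminal removal driven by strict-consensus gain.

    Each round scores every unprotected terminal by the increase in
    strict-consensus resolution (non-root internal edge count) obtained by
    pruning it from every tree, removes the best-scoring terminal when the
    gain reaches ``min_gain`` (ties broken by lexicographic label), and stops
    at ``max_rounds`` or when no candidate qualifies.  The subjective
    trade-off of manual wildcard deletion is replaced by this explicit
    (min_gain, max_rounds, protected) stopping contract.  The Adams consensus
    of each round is emitted for inspection but never scored.
    """
    if min_gain < 1:
        raise ValueError("min_gain must be >= 1")
    protected = frozenset(protected)
    if not protected <= trees.leaf_set:
        raise ValueError("protected labels not in the tree set")
    current = trees
    initial_strict = strict_consensus(current)
    initial_adams = adams_consensus(current)
    base_res = initial_strict.resolution()
    removed, rounds = [], []
    blocked = None
    while max_rounds is None or len(removed) < max_rounds:
        candidates = sorted(current.leaf_set)
        if len(candidates) <= 2:
            break
        best_label, best_gain = None, 0
        best_blocked = None
        for label in candidates:
            pruned = prune_terminals(current, {label})
            gain = strict_consensus(pruned).resolution() - base_res
            if label in protected:
                if best_blocked is None or gain > best_blocked[1]:
                    best_blocked = (label, gain)
                continue
            if gain > best_gain:
                best_label, best_gain = label, gain
        if best_label is None or best_gain < min_gain:
            if best_blocked is not None and best_blocked[1] >= min_gain:
                blocked = best_blocked
            break
        current = prune_terminals(current, {best_label})
        strict = strict_consensus(current)
        base_res = strict.resolution()
        removed.append(best_label)
        rounds.append(
            WildcardRound(
                removed=best_label,
                gain=best_gain,
                resolution=base_res,
                strict=strict,
                adams=adams_consensus(current),
            )
        )
    return WildcardScanResult(
        removed=removed,
        rounds=rounds,
        initial_resolution=initial_strict.resolution(),
        initial_strict=initial_strict,
        initial_adams=initial_adams,
        blocked_candidate=blocked,
        final_trees=current,
    )


# ---------------------------------------------------------------------------
# Monophyly


@dataclass
class MonophylyRecord:
    species: str
    status: str  # monophyletic | non-monophyletic | not-assessed
    support: float = None  # percent of replicate trees with the clade
    n_sampled: int = 0


def monophyly_support(
    replicates: TreeSet, grouping: GroupingMap, primary_index: int = 0
) -> list:
    """Per-species monophyly status and replicate support.

    Support = 100 x (replicate trees in which the species' sampled leaves
    form a cluster) / (number of trees).  Status comes from the designated
    primary tree (by default the first).  Species with fewer than two sampled
    leaves are not assessed.
    """
    leaf_species: dict = {}
    for leaf in replicates.leaf_set:
        if leaf in grouping.terminal_to_population:
            leaf_species.setdefault(grouping.species_of(leaf), set()).add(leaf)
    records = []
    cluster_cache = [t.clusters() for t in replicates]
    for sp in grouping.species:
        sampled = frozenset(leaf_species.get(sp, set()))
        if len(sampled) < 2:
            records.append(
                MonophylyRecord(sp, "not-assessed", None, len(sampled))
            )
            continue
        hits = sum(
            1
            for cl in cluster_cache
            if sampled in cl or sampled == replicates.leaf_set
        )
        support = 100.0 * hits / len(replicates)
        primary = cluster_cache[primary_index]
        mono = sampled in primary or sampled == replicates.leaf_set
        records.append(
            MonophylyRecord(
                sp,
                "monophyletic" if mono else "non-monophyletic",
                support,
                len(sampled),
            )
        )
    return records
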