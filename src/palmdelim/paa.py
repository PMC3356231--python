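"""Population aggregation analysis (PAA).

Diagnosability under the first phylogenetic species concept: two units
(terminals, populations, or putative species) are kept apart when at least
one character shows mutually exclusive (disjoint) observed state sets --
evidence that gene flow between them has ceased.  Units whose profiles lack
any such fixed difference are aggregated, the merged profile is re-compared
against every other profile, and the process repeats to a fixed point.

Missing data never create or block a diagnostic: profiles are built from
non-missing member cells only, a character observed in neither unit (or only
one) is simply not diagnostic, and terminals that are missing at characters
diagnostic for their final group are sequestered and reported rather than
allowed to trigger merges.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .matrices import MISSING, CharacterMatrix, GroupingMap

__all__ = [
    "PopulationProfile",
    "AggregationResult",
    "build_profiles",
    "diagnostic_characters",
    "aggregate_profiles",
    "oracle_aggregate",
]

SEQUESTERED_GROUP_LABEL = "sequestered"


@dataclass
class PopulationProfile:
    """Observed state sets of one unit, with per-terminal missing records."""

    unit: str
    character_ids: list
    states: dict  # char id -> frozenset of observed states (may be empty)
    members: list  # member terminal identifiers
    member_missing: dict = field(default_factory=dict)  # terminal -> set of char ids

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"unit {self.unit!r} has no members")

    def missing_only(self, char_id: str) -> bool:
        return not self.states[char_id]

    def merged_with(self, other: "PopulationProfile", unit: str) -> "PopulationProfile":
        if self.character_ids != other.character_ids:
            raise ValueError("profiles over different character lists")
        states = {
            c: self.states[c] | other.states[c] for c in self.character_ids
        }
        mm = {t: set(v) for t, v in self.member_missing.items()}
        for t, v in other.member_missing.items():
            mm.setdefault(t, set()).update(v)
        return PopulationProfile(
            unit, self.character_ids, states, self.members + other.members, mm
        )


def build_profiles(
    matrix: CharacterMatrix, grouping: GroupingMap, level: str = "population"
) -> list:
    """Build per-unit profiles: character-wise unions of non-missing cells."""
    grouping.check_total(matrix.terminals)
    units: dict = {}
    for t in matrix.terminals:
        units.setdefault(grouping.unit_of(t, level), []).append(t)
    char_ids = matrix.character_ids
    profiles = []
    for unit, members in units.items():
        states = {c: frozenset() for c in char_ids}
        member_missing: dict = {}
        for t in members:
            for c in char_ids:
                v = matrix.cell(t, c)
                if v is MISSING:
                    member_missing.setdefault(t, set()).add(c)
                else:
                    states[c] = states[c] | v
        profiles.append(
            PopulationProfile(unit, char_ids, states, members, member_missing)
        )
    return profiles


def diagnostic_characters(p: PopulationProfile, q: PopulationProfile) -> list:
    """Characters whose observed state sets are disjoint and both present."""
    if p.character_ids != q.character_ids:
        raise ValueError("profiles over different character lists")
    out = []
    for c in p.character_ids:
        sp, sq = p.states[c], q.states[c]
        if sp and sq and not (sp & sq):
            out.append(c)
    return out


@dataclass
class AggregationResult:
    """Fixed-point partition with diagnostic evidence and sequestration."""

    groups: list  # final PopulationProfiles (merged)
    group_units: dict  # group label -> list of original unit ids
    pair_diagnostics: dict  # (label_i, label_j) ordered -> list of char ids
    sequestered: list  # (terminal, group label, sorted char ids)
    sequester_policy: str = "set-aside"
    merge_log: list = field(default_factory=list)  # (unit_a, unit_b, merged label)

    @property
    def partition(self) -> frozenset:
        return frozenset(
            frozenset(units) for units in self.group_units.values()
        )

    def group_of_unit(self, unit: str) -> str:
        for label, units in self.group_units.items():
            if unit in units:
                return label
        raise KeyError(unit)


def _merged_label(units) -> str:
    return "+".join(sorted(units))


def aggregate_profiles(profiles: list, sequester_policy: str = "set-aside") -> AggregationResult:
    """Aggregate profiles to the fixed point of diagnosability.

    Repeatedly merges any pair of groups with zero diagnostic characters
    (merged profile = character-wise union) until every remaining pair is
    separated by at least one diagnostic.  Scan order is deterministic
    (input order, pairs lexicographic by index); order invariance is a tested
    property, not an assumption.

    Terminals missing at characters diagnostic for their final group are
    sequestered: ``set-aside`` lists them, ``single-group`` additionally
    collects them under one labelled pseudo-group, mirroring the treatment of
    arbitrarily assigning such terminals to a single group instead of letting
    them collapse otherwise diagnosable groups.
    """
    if sequester_policy not in ("set-aside", "single-group"):
        raise ValueError(f"unknown sequester policy {sequester_policy!r}")
    if not profiles:
        raise ValueError("need at least one profile")
    current = list(profiles)
    units_of = {p.unit: [p.unit] for p in current}
    merge_log = []
    changed = True
    while changed:
        changed = False
        for i, j in itertools.combinations(range(len(current)), 2):
            if not diagnostic_characters(current[i], current[j]):
                a, b = current[i], current[j]
                merged_units = units_of.pop(a.unit) + units_of.pop(b.unit)
                label = _merged_label(merged_units)
                merged = a.merged_with(b, label)
                units_of[label] = merged_units
                merge_log.append((a.unit, b.unit, label))
                current = [p for k, p in enumerate(current) if k not in (i, j)]
                current.append(merged)
                changed = True
                break
    pair_diags = {}
    for a, b in itertools.permutations(current, 2):
        pair_diags[(a.unit, b.unit)] = diagnostic_characters(a, b)
    sequestered = []
    for p in current:
        group_diag = set()
        for q in current:
            if q is not p:
                group_diag.update(pair_diags[(p.unit, q.unit)])
        for t in p.members:
            miss = p.member_missing.get(t, set()) & group_diag
            if miss:
                sequestered.append((t, p.unit, sorted(miss)))
    return AggregationResult(
        groups=current,
        group_units={p.unit: units_of[p.unit] for p in current},
        pair_diagnostics=pair_diags,
        sequestered=sequestered,
        sequester_policy=sequester_policy,
        merge_log=merge_log,
    )


def oracle_aggregate(profiles: list, max_units: int = 6) -> set:
    """Exhaustive merge-order oracle: all reachable fixed-point partitions.

    Explores every possible order of pairwise merges and returns the set of
    distinct fixed points, each a frozenset of frozensets of unit ids.  Only
    feasible for small instances; used to verify that the deterministic
    aggregation is order-independent (the oracle set should be a singleton).
    """
    if len(profiles) > max_units:
        raise ValueError(f"oracle limited to {max_units} units")
    base = {p.unit: p for p in profiles}

    results: set = set()
    seen: set = set()

    def profile_for(block: frozenset) -> PopulationProfile:
        members = sorted(block)
        prof = base[members[0]]
        for u in members[1:]:
            prof = prof.merged_with(base[u], _merged_label(block))
        return prof

    def explore(partition: frozenset):
        if partition in seen:
            return
        seen.add(partition)
        profs = {block: profile_for(block) for block in partition}
        mergeable = [
            (x, y)
            for x, y in itertools.combinations(sorted(partition, key=sorted), 2)
            if not diagnostic_characters(profs[x], profs[y])
        ]
        if not mergeable:
            results.add(partition)
            return
        for x, y in mergeable:
            nxt = (partition - {x, y}) | {x | y}
            explore(frozenset(nxt))

    explore(frozenset(frozenset({p.unit}) for p in profiles))
    return results
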