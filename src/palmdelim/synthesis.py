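"""Per-lineage conformance synthesis under the general lineage species concept.

Combines the three operational criteria -- monophyly (with replicate
support), genotypic clustering (modal cluster, membership coefficient,
necessity/exclusivity), and diagnosability by mutually exclusive character
states -- into one table with a criteria-satisfied count per putative
lineage.  The more criteria a lineage satisfies, the stronger the evidence
that it is a separately evolving lineage.

A transcription of the published Hawaiian *Pritchardia* conformance table
ships with the package (``data/table1_pritchardia.tsv``) and can be
re-tallied through the same code paths.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

from .clusters import GSCRecord
from .matrices import GroupingMap, _source_text
from .paa import AggregationResult
from .trees import MonophylyRecord

__all__ = [
    "YES",
    "NO",
    "NOT_ASSESSED",
    "YES_SUBSTRUCTURE",
    "ConformanceRow",
    "ConformanceTable",
    "ConformanceParseError",
    "assemble_conformance",
    "read_conformance",
    "render_conformance",
    "tally_criteria",
    "Tally",
    "packaged_table1",
]

YES = "yes"
NO = "no"
NOT_ASSESSED = "not-assessed"
YES_SUBSTRUCTURE = "yes-with-substructure"  # lineage splits into several pure groups


class ConformanceParseError(ValueError):
    """Unparseable cell in a conformance table, reported with row/column."""


@dataclass
class ConformanceRow:
    lineage: str
    monophyly: str = NOT_ASSESSED  # yes / no / not-assessed
    monophyly_support: float = None  # percent
    gsc_cluster: int = None
    gsc_coefficient: float = None
    gsc_necessary: bool = None
    gsc_satisfied: str = NOT_ASSESSED  # yes / no / not-assessed
    diagnosable: str = NOT_ASSESSED  # yes / yes-with-substructure / no / not-assessed

    @property
    def criteria_count(self) -> int:
        """Number of satisfied criteria; not-assessed never counts either way."""
        count = 0
        if self.monophyly == YES:
            count += 1
        if self.gsc_satisfied == YES:
            count += 1
        if self.diagnosable in (YES, YES_SUBSTRUCTURE):
            count += 1
        return count

    @property
    def n_assessed(self) -> int:
        return sum(
            1
            for v in (self.monophyly, self.gsc_satisfied, self.diagnosable)
            if v != NOT_ASSESSED
        )


@dataclass
class ConformanceTable:
    rows: list = field(default_factory=list)

    def __post_init__(self):
        keys = [r.lineage for r in self.rows]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate lineage keys in conformance table")

    def __len__(self):
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def row(self, lineage: str) -> ConformanceRow:
        for r in self.rows:
            if r.lineage == lineage:
                return r
        raise KeyError(lineage)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "lineage": [r.lineage for r in self.rows],
                "monophyly": [r.monophyly for r in self.rows],
                "monophyly_support": [r.monophyly_support for r in self.rows],
                "gsc_cluster": [r.gsc_cluster for r in self.rows],
                "gsc_coefficient": [r.gsc_coefficient for r in self.rows],
                "gsc_necessary": [r.gsc_necessary for r in self.rows],
                "gsc_satisfied": [r.gsc_satisfied for r in self.rows],
                "diagnosable": [r.diagnosable for r in self.rows],
                "criteria_count": [r.criteria_count for r in self.rows],
            }
        )


def _norm_key(key: str) -> str:
    return " ".join(key.split()).strip().lower()


def assemble_conformance(
    mono: list,
    gsc: list,
    paa: AggregationResult,
    unit_to_lineage: dict,
) -> ConformanceTable:
    """Assemble the three criteria into one per-lineage table.

    ``unit_to_lineage`` maps the aggregation's original units to putative
    lineages (identity when aggregation ran at species level).  A lineage is
    diagnosable when its units fall only in groups containing no other
    lineage's units (with a distinct ``yes-with-substructure`` verdict when
    they split over several such groups -- over-splitting, not failure);
    the genotypic-cluster criterion is satisfied when necessary and
    exclusive; monophyly when the primary-tree status is monophyletic.
    Lineages absent from a source are not assessed for that criterion.
    """
    mono_by: dict = {}
    for m in mono:
        key = _norm_key(m.species)
        if key in mono_by and mono_by[key].status != m.status:
            raise ValueError(f"conflicting duplicate monophyly records: {m.species!r}")
        mono_by[key] = m
    gsc_by: dict = {}
    for g in gsc:
        key = _norm_key(g.species)
        if key in gsc_by:
            raise ValueError(f"conflicting duplicate GSC records: {g.species!r}")
        gsc_by[key] = g
    lineages: list = []
    for src in (
        [m.species for m in mono],
        [g.species for g in gsc],
        list(unit_to_lineage.values()),
    ):
        for name in src:
            if _norm_key(name) not in [_norm_key(x) for x in lineages]:
                lineages.append(name)

    # group purity for diagnosability
    lineage_groups: dict = {}
    group_lineages: dict = {}
    for label, units in paa.group_units.items():
        ls = {_norm_key(unit_to_lineage[u]) for u in units if u in unit_to_lineage}
        group_lineages[label] = ls
        for l in ls:
            lineage_groups.setdefault(l, set()).add(label)

    rows = []
    for name in lineages:
        key = _norm_key(name)
        row = ConformanceRow(lineage=name)
        m = mono_by.get(key)
        if m is not None and m.status != "not-assessed":
            row.monophyly = YES if m.status == "monophyletic" else NO
            row.monophyly_support = m.support
        g = gsc_by.get(key)
        if g is not None and g.assessed:
            row.gsc_cluster = g.modal_cluster
            row.gsc_coefficient = g.mean_coefficient
            row.gsc_necessary = g.necessary
            row.gsc_satisfied = YES if g.satisfied else NO
        groups = lineage_groups.get(key)
        if groups:
            pure = all(group_lineages[lab] == {key} for lab in groups)
            if not pure:
                row.diagnosable = NO
            elif len(groups) > 1:
                row.diagnosable = YES_SUBSTRUCTURE
            else:
                row.diagnosable = YES
        rows.append(row)
    return ConformanceTable(rows)


# ---------------------------------------------------------------------------
# Tabular I/O


def _parse_mono_cell(cell: str, rowno: int):
    c = cell.strip()
    if c in ("-", ""):
        return NOT_ASSESSED, None
    if c.lower() == "no":
        return NO, None
    if c.endswith("%"):
        try:
            return YES, float(c[:-1])
        except ValueError:
            pass
    raise ConformanceParseError(
        f"row {rowno}, column 'monophyletic': cannot parse {cell!r}"
    )


def _parse_gsc_cell(cell: str, rowno: int):
    c = cell.strip()
    if c in ("-", ""):
        return None, None
    if ";" in c:
        left, right = c.split(";", 1)
        try:
            return int(left.strip()), float(right.strip())
        except ValueError:
            pass
    raise ConformanceParseError(
        f"row {rowno}, column 'genotypic_cluster': cannot parse {cell!r}"
    )


def _parse_diag_cell(cell: str, rowno: int):
    c = cell.strip().lower()
    if c in ("-", ""):
        return NOT_ASSESSED
    if c == "yes":
        return YES
    if c == "no":
        return NO
    if c == YES_SUBSTRUCTURE:
        return YES_SUBSTRUCTURE
    raise ConformanceParseError(
        f"row {rowno}, column 'diagnosable': cannot parse {cell!r}"
    )


def read_conformance(source) -> ConformanceTable:
    """Read a conformance TSV.

    Required columns: ``lineage``, ``monophyletic`` (a percentage for a
    supported clade, ``No``, or ``-``), ``genotypic_cluster`` (``"12; 0.91"``
    or ``-``), ``diagnosable`` (``Yes``/``No``/``-``).  An optional
    ``gsc_satisfied`` column (``yes``/``no``/``-``) carries the
    necessary-and-sufficient verdict where the coefficient alone cannot
    (a lineage can exceed the membership threshold without being exclusive);
    absent that column, the verdict falls back to coefficient > 0.8.
    """
    text = _source_text(source)
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    required = ("lineage", "monophyletic", "genotypic_cluster", "diagnosable")
    for col in required:
        if col not in header:
            raise ConformanceParseError(f"missing column {col!r}")
    idx = {col: header.index(col) for col in header}
    has_sat = "gsc_satisfied" in idx
    rows = []
    for rowno, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != len(header):
            raise ConformanceParseError(f"row {rowno}: wrong field count")
        lineage = parts[idx["lineage"]].strip()
        mono, support = _parse_mono_cell(parts[idx["monophyletic"]], rowno)
        cluster, coeff = _parse_gsc_cell(parts[idx["genotypic_cluster"]], rowno)
        diag = _parse_diag_cell(parts[idx["diagnosable"]], rowno)
        if has_sat:
            sat = _parse_diag_cell(parts[idx["gsc_satisfied"]], rowno)
        elif coeff is None:
            sat = NOT_ASSESSED
        else:
            sat = YES if coeff > 0.8 else NO
        rows.append(
            ConformanceRow(
                lineage=lineage,
                monophyly=mono,
                monophyly_support=support,
                gsc_cluster=cluster,
                gsc_coefficient=coeff,
                gsc_necessary=None if coeff is None else coeff > 0.8,
                gsc_satisfied=sat if cluster is not None else NOT_ASSESSED,
                diagnosable=diag,
            )
        )
    return ConformanceTable(rows)


def render_conformance(table: ConformanceTable, format: str = "tsv") -> str:
    """Render a table back to text; inverse of :func:`read_conformance`."""
    header = [
        "lineage",
        "monophyletic",
        "genotypic_cluster",
        "gsc_satisfied",
        "diagnosable",
    ]

    def cells(r: ConformanceRow):
        mono = (
            "-"
            if r.monophyly == NOT_ASSESSED
            else ("No" if r.monophyly == NO else f"{r.monophyly_support:g}%")
        )
        gsc = (
            "-"
            if r.gsc_cluster is None
            else f"{r.gsc_cluster}; {r.gsc_coefficient:.2f}"
        )
        sat = "-" if r.gsc_satisfied == NOT_ASSESSED else r.gsc_satisfied
        diag = (
            "-"
            if r.diagnosable == NOT_ASSESSED
            else ("Yes" if r.diagnosable == YES else
                  (r.diagnosable if r.diagnosable == YES_SUBSTRUCTURE else "No"))
        )
        return [r.lineage, mono, gsc, sat, diag]

    if format == "tsv":
        out = ["\t".join(header)]
        out += ["\t".join(cells(r)) for r in table]
        return "\n".join(out) + "\n"
    if format == "markdown":
        out = ["| " + " | ".join(header) + " |"]
        out.append("|" + "---|" * len(header))
        out += ["| " + " | ".join(cells(r)) + " |" for r in table]
        return "\n".join(out) + "\n"
    raise ValueError(f"unknown format {format!r}")


@dataclass
class Tally:
    n_rows: int
    by_count: dict  # criteria-count level -> number of lineages
    monophyletic: int
    gsc_satisfied: int
    gsc_necessary: int
    diagnosable: int
    coefficient_above: int = None
    coefficient_threshold: float = None


def tally_criteria(table: ConformanceTable, coefficient_threshold: float = 0.8) -> Tally:
    """Deterministic tallies over a conformance table.

    ``coefficient_above`` counts rows whose parsed membership coefficient is
    strictly greater than ``coefficient_threshold``.
    """
    by_count = {i: 0 for i in range(4)}
    for r in table:
        by_count[r.criteria_count] += 1
    return Tally(
        n_rows=len(table),
        by_count=by_count,
        monophyletic=sum(1 for r in table if r.monophyly == YES),
        gsc_satisfied=sum(1 for r in table if r.gsc_satisfied == YES),
        gsc_necessary=sum(1 for r in table if r.gsc_necessary),
        diagnosable=sum(
            1 for r in table if r.diagnosable in (YES, YES_SUBSTRUCTURE)
        ),
        coefficient_above=sum(
            1
            for r in table
            if r.gsc_coefficient is not None
            and r.gsc_coefficient > coefficient_threshold
        ),
        coefficient_threshold=coefficient_threshold,
    )


def packaged_table1() -> ConformanceTable:
    """The packaged transcription of the published conformance table."""
    ref = importlib.resources.files("palmdelim").joinpath(
        "data/table1_pritchardia.tsv"
    )
    return read_conformance(ref.read_text())
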