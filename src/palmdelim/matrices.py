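"""Multistate character matrices.

The substrate for diagnosability analysis: a terminals x characters grid in
which each cell is either a non-empty set of state symbols (a singleton for an
ordinary observation, a larger set for a polymorphic/ambiguous observation)
or MISSING.  Three character classes are distinguished -- DNA sequence sites,
microsatellite loci coded as multistate characters (heterozygotes become
subset polymorphisms, i.e. the two-allele state set), and morphological
characters.

I/O formats: NEXUS DATA/CHARACTERS blocks (brace polymorphism, '?' missing,
single-character symbols; parsed through dendropy) and a TSV layout that also
carries per-character class tags and alphabets so that arbitrary symbols such
as binned microsatellite allele sizes round-trip losslessly.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy

__all__ = [
    "MISSING",
    "Character",
    "CharacterMatrix",
    "GroupingMap",
    "MatrixFormatError",
    "DuplicateTerminalError",
    "UnknownStateError",
    "HalfMissingGenotypeError",
    "read_matrix",
    "write_matrix",
    "read_grouping",
    "encode_microsatellite_genotypes",
    "make_composite",
    "classify_characters",
    "CharacterClassification",
]

SEQUENCE = "sequence-site"
MICROSATELLITE = "microsatellite-locus"
MORPHOLOGICAL = "morphological"
CHARACTER_CLASSES = (SEQUENCE, MICROSATELLITE, MORPHOLOGICAL)


class _Missing:
    """Sentinel for a missing cell; distinct from every state set."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "MISSING"

    def __bool__(self):
        return False


MISSING = _Missing()


class MatrixFormatError(ValueError):
    """Malformed matrix block or row."""


class DuplicateTerminalError(MatrixFormatError):
    """The same terminal identifier appears twice."""


class UnknownStateError(MatrixFormatError):
    """A cell uses a symbol outside the character's declared alphabet."""


class HalfMissingGenotypeError(ValueError):
    """A genotype with one missing and one observed allele, no policy set."""


@dataclass(frozen=True)
class Character:
    """One column: identifier, class tag, and declared state alphabet."""

    id: str
    klass: str = SEQUENCE
    alphabet: frozenset = frozenset()

    def __post_init__(self):
        if self.klass not in CHARACTER_CLASSES:
            raise ValueError(f"unknown character class {self.klass!r}")


class CharacterMatrix:
    """Terminals x characters grid of state sets or MISSING.

    Invariants enforced on construction: unique terminal identifiers, exactly
    one cell per (terminal, character), every cell symbol inside the
    character's alphabet, cells are non-empty frozensets or MISSING.
    """

    def __init__(
        self,
        terminals: Sequence[str],
        characters: Sequence[Character],
        cells: Mapping[tuple, object],
    ):
        terminals = list(terminals)
        if len(set(terminals)) != len(terminals):
            dup = sorted({t for t in terminals if terminals.count(t) > 1})
            raise DuplicateTerminalError(f"duplicate terminal(s): {dup}")
        self.terminals = terminals
        self.characters = list(characters)
        char_ids = [c.id for c in self.characters]
        if len(set(char_ids)) != len(char_ids):
            raise MatrixFormatError("duplicate character identifiers")
        self._by_id = {c.id: c for c in self.characters}
        self._cells: dict = {}
        for t in terminals:
            for c in self.characters:
                key = (t, c.id)
                if key not in cells:
                    raise MatrixFormatError(f"no cell for {key}")
                val = cells[key]
                if val is not MISSING:
                    val = frozenset(str(s) for s in val)
                    if not val:
                        raise MatrixFormatError(f"empty state set at {key}")
                    bad = val - c.alphabet
                    if bad:
                        raise UnknownStateError(
                            f"symbol(s) {sorted(bad)} at {key} outside "
                            f"alphabet of character {c.id!r}"
                        )
                self._cells[key] = val
        extra = set(cells) - set(self._cells)
        if extra:
            raise MatrixFormatError(f"cells outside the grid: {sorted(extra)[:3]}")

    def cell(self, terminal: str, character_id: str):
        return self._cells[(terminal, character_id)]

    def character(self, character_id: str) -> Character:
        return self._by_id[character_id]

    @property
    def character_ids(self):
        return [c.id for c in self.characters]

    def __eq__(self, other):
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            self.terminals == other.terminals
            and self.characters == other.characters
            and self._cells == other._cells
        )

    def __repr__(self):
        return (
            f"<CharacterMatrix {len(self.terminals)} terminals x "
            f"{len(self.characters)} characters>"
        )

    def subset_terminals(self, keep: Iterable[str]) -> "CharacterMatrix":
        keep = [t for t in self.terminals if t in set(keep)]
        cells = {
            (t, c.id): self._cells[(t, c.id)] for t in keep for c in self.characters
        }
        return CharacterMatrix(keep, self.characters, cells)

    def concat(self, other: "CharacterMatrix") -> "CharacterMatrix":
        """Column-wise concatenation on the intersection of terminals.

        Used for cross-dataset diagnosability: characters from both matrices
        are read jointly over the shared terminals.
        """
        shared = [t for t in self.terminals if t in set(other.terminals)]
        if not shared:
            raise MatrixFormatError("no shared terminals to concatenate on")
        chars = self.characters + [
            c for c in other.characters if c.id not in self._by_id
        ]
        if len(chars) != len(self.characters) + len(other.characters):
            raise MatrixFormatError("overlapping character identifiers")
        cells = {}
        for t in shared:
            for c in self.characters:
                cells[(t, c.id)] = self._cells[(t, c.id)]
            for c in other.characters:
                cells[(t, c.id)] = other._cells[(t, c.id)]
        return CharacterMatrix(shared, chars, cells)


@dataclass
class GroupingMap:
    """terminal -> population -> putative species, total over a matrix."""

    terminal_to_population: dict
    population_to_species: dict

    def __post_init__(self):
        missing = set(self.terminal_to_population.values()) - set(
            self.population_to_species
        )
        if missing:
            raise ValueError(f"populations without a species: {sorted(missing)}")

    def population_of(self, terminal: str) -> str:
        return self.terminal_to_population[terminal]

    def species_of(self, terminal: str) -> str:
        return self.population_to_species[self.terminal_to_population[terminal]]

    @property
    def species(self):
        seen = []
        for pop in self.population_to_species:
            sp = self.population_to_species[pop]
            if sp not in seen:
                seen.append(sp)
        return seen

    def unit_of(self, terminal: str, level: str) -> str:
        if level == "terminal":
            return terminal
        if level == "population":
            return self.population_of(terminal)
        if level == "species":
            return self.species_of(terminal)
        raise ValueError(f"unknown level {level!r}")

    def check_total(self, terminals: Iterable[str]):
        missing = [t for t in terminals if t not in self.terminal_to_population]
        if missing:
            raise ValueError(f"terminals not covered by grouping: {missing[:5]}")


def read_grouping(source) -> GroupingMap:
    """Read a terminal/population/species TSV (header required)."""
    import pandas as pd

    df = pd.read_csv(_as_path_or_buffer(source), sep="\t", dtype=str)
    for col in ("terminal", "population", "species"):
        if col not in df.columns:
            raise MatrixFormatError(f"grouping table lacks column {col!r}")
    t2p = dict(zip(df["terminal"], df["population"]))
    p2s = {}
    for pop, sp in zip(df["population"], df["species"]):
        if pop in p2s and p2s[pop] != sp:
            raise MatrixFormatError(f"population {pop!r} mapped to two species")
        p2s[pop] = sp
    return GroupingMap(t2p, p2s)


# ---------------------------------------------------------------------------
# I/O


def _as_path_or_buffer(source):
    if isinstance(source, (str, os.PathLike)) and os.path.exists(source):
        return source
    if isinstance(source, str):
        return io.StringIO(source)
    return source


def _source_text(source) -> str:
    if isinstance(source, (str, os.PathLike)) and os.path.exists(source):
        with open(source) as fh:
            return fh.read()
    if isinstance(source, str):
        return source
    return source.read()


def read_matrix(
    source,
    format: str = "nexus",
    char_class: str = SEQUENCE,
    gap_as_missing: bool = True,
) -> CharacterMatrix:
    """Read a multistate character matrix.

    ``format='nexus'``: a DATA/CHARACTERS block with DATATYPE=STANDARD,
    brace-enclosed polymorphism and '?' missing; all characters receive the
    block's symbol list as alphabet and ``char_class`` as class tag.  The gap
    symbol '-' is treated as missing by default (``gap_as_missing=False``
    scores it as a fifth state, added to the alphabet).

    ``format='tsv'``: the package's TSV layout (see :func:`write_matrix`).
    """
    if format == "nexus":
        return _read_nexus(_source_text(source), char_class, gap_as_missing)
    if format == "tsv":
        return _read_tsv(_source_text(source))
    raise ValueError(f"unknown format {format!r}")


import re as _re

_SYMBOLS_RE = _re.compile(r'SYMBOLS\s*=\s*"([^"]+)"', _re.IGNORECASE)


def _nexus_row_labels(text: str):
    m = _re.search(r"MATRIX(.*?);", text, _re.IGNORECASE | _re.DOTALL)
    if not m:
        return []
    labels = []
    for line in m.group(1).splitlines():
        line = line.strip()
        if line:
            labels.append(line.split()[0].strip("'"))
    return labels


def _read_nexus(text: str, char_class: str, gap_as_missing: bool) -> CharacterMatrix:
    try:
        dmat = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    except Exception as exc:  # dendropy raises assorted error types
        labels = _nexus_row_labels(text)
        if len(labels) != len(set(labels)):
            raise DuplicateTerminalError(
                f"duplicate terminal row(s) in NEXUS matrix"
            ) from exc
        raise MatrixFormatError(f"malformed NEXUS matrix: {exc}") from exc
    labels = [tax.label for tax in dmat.taxon_namespace]
    if len(set(labels)) != len(labels):
        raise DuplicateTerminalError(f"duplicate terminals in NEXUS: {labels}")
    alphabet = set()
    rows = {}
    for tax in dmat:
        seq = dmat[tax]
        states = []
        for ch in seq:
            sym = ch.symbol
            members = [s.symbol for s in ch.member_states] if ch.member_states else []
            if sym == "?":
                states.append(MISSING)
            elif sym == "-":
                states.append(MISSING if gap_as_missing else frozenset({"-"}))
            elif members and len(members) > 1:
                states.append(frozenset(members))
            else:
                states.append(frozenset({sym}))
        rows[tax.label] = states
        for st in states:
            if st is not MISSING:
                alphabet |= st
    ncols = {len(v) for v in rows.values()}
    if len(ncols) != 1:
        raise MatrixFormatError("ragged NEXUS matrix rows")
    ncols = ncols.pop()
    declared = _SYMBOLS_RE.search(text)
    if declared:
        alphabet |= set(declared.group(1))
    alpha = frozenset(alphabet)
    chars = [Character(f"c{i + 1}", char_class, alpha) for i in range(ncols)]
    cells = {
        (t, chars[i].id): rows[t][i] for t in labels for i in range(ncols)
    }
    return CharacterMatrix(labels, chars, cells)


def _read_tsv(text: str) -> CharacterMatrix:
    lines = [ln.rstrip("\n") for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise MatrixFormatError("empty TSV matrix")
    header = lines[0].split("\t")
    if header[0] != "terminal":
        raise MatrixFormatError("TSV header must start with 'terminal'")
    char_ids = header[1:]
    classes = {cid: SEQUENCE for cid in char_ids}
    alphabets = {cid: None for cid in char_ids}
    data_lines = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        if parts[0] == "#class":
            for cid, k in zip(char_ids, parts[1:]):
                classes[cid] = k
        elif parts[0] == "#alphabet":
            for cid, a in zip(char_ids, parts[1:]):
                alphabets[cid] = frozenset(a.split(",")) if a else frozenset()
        else:
            data_lines.append(parts)
    seen = set()
    rows = {}
    order = []
    for parts in data_lines:
        if len(parts) != len(char_ids) + 1:
            raise MatrixFormatError(f"row {parts[0]!r}: wrong cell count")
        term = parts[0]
        if term in seen:
            raise DuplicateTerminalError(f"duplicate terminal {term!r}")
        seen.add(term)
        order.append(term)
        row = []
        for cell in parts[1:]:
            if cell == "?":
                row.append(MISSING)
            else:
                row.append(frozenset(cell.split(",")))
        rows[term] = row
    for cid in char_ids:
        if alphabets[cid] is None:
            observed = set()
            for term in order:
                st = rows[term][char_ids.index(cid)]
                if st is not MISSING:
                    observed |= st
            alphabets[cid] = frozenset(observed)
    chars = [Character(cid, classes[cid], alphabets[cid]) for cid in char_ids]
    cells = {
        (t, cid): rows[t][i] for t in order for i, cid in enumerate(char_ids)
    }
    return CharacterMatrix(order, chars, cells)


def write_matrix(matrix: CharacterMatrix, format: str = "tsv") -> str:
    """Serialize; ``read_matrix(write_matrix(m), format)`` is the identity.

    For NEXUS the identity additionally requires single-character symbols, a
    uniform class tag, and a shared alphabet (NEXUS declares one symbol list
    for the whole block).
    """
    if format == "tsv":
        return _write_tsv(matrix)
    if format == "nexus":
        return _write_nexus(matrix)
    raise ValueError(f"unknown format {format!r}")


def _write_tsv(matrix: CharacterMatrix) -> str:
    out = ["terminal\t" + "\t".join(matrix.character_ids)]
    out.append("#class\t" + "\t".join(c.klass for c in matrix.characters))
    out.append(
        "#alphabet\t"
        + "\t".join(",".join(sorted(c.alphabet)) for c in matrix.characters)
    )
    for t in matrix.terminals:
        cells = []
        for c in matrix.characters:
            v = matrix.cell(t, c.id)
            cells.append("?" if v is MISSING else ",".join(sorted(v)))
        out.append(t + "\t" + "\t".join(cells))
    return "\n".join(out) + "\n"


def _write_nexus(matrix: CharacterMatrix) -> str:
    symbols = sorted(set().union(*(c.alphabet for c in matrix.characters)))
    if any(len(s) != 1 for s in symbols):
        raise MatrixFormatError(
            "NEXUS output needs single-character symbols; use TSV"
        )
    width = max(len(t) for t in matrix.terminals) + 2
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"DIMENSIONS NTAX={len(matrix.terminals)} NCHAR={len(matrix.characters)};",
        f'FORMAT DATATYPE=STANDARD SYMBOLS="{"".join(symbols)}" MISSING=? GAP=-;',
        "MATRIX",
    ]
    for t in matrix.terminals:
        cells = []
        for c in matrix.characters:
            v = matrix.cell(t, c.id)
            if v is MISSING:
                cells.append("?")
            elif len(v) == 1:
                cells.append(next(iter(v)))
            else:
                cells.append("{" + "".join(sorted(v)) + "}")
        label = f"'{t}'" if any(ch.isspace() for ch in t) else t
        lines.append(label.ljust(width) + "".join(cells))
    lines += [";", "END;", ""]
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Encoding and derived matrices


def encode_microsatellite_genotypes(
    genotype_table: Mapping[str, Mapping[str, tuple]],
    missing_code: int = -9,
    half_missing: str = "reject",
) -> CharacterMatrix:
    """Code diploid microsatellite genotypes as multistate characters.

    Each locus becomes one character whose states are the (already binned)
    allele sizes; a heterozygote (a, b) is coded as the subset polymorphism
    {a, b}, a homozygote (a, a) as {a}, and a genotype with both alleles equal
    to ``missing_code`` as MISSING.  A half-missing genotype (one allele
    observed) is rejected unless ``half_missing='keep-observed'``, which keeps
    the observed allele as a singleton.
    """
    if half_missing not in ("reject", "keep-observed"):
        raise ValueError(f"unknown half-missing policy {half_missing!r}")
    terminals = list(genotype_table)
    loci: list = []
    for row in genotype_table.values():
        for locus in row:
            if locus not in loci:
                loci.append(locus)
    cells = {}
    alphabets = {locus: set() for locus in loci}
    for term in terminals:
        row = genotype_table[term]
        for locus in loci:
            if locus not in row:
                cells[(term, locus)] = MISSING
                continue
            a, b = row[locus]
            a_miss, b_miss = a == missing_code, b == missing_code
            if a_miss and b_miss:
                cells[(term, locus)] = MISSING
            elif a_miss or b_miss:
                if half_missing == "reject":
                    raise HalfMissingGenotypeError(
                        f"terminal {term!r}, locus {locus!r}: one allele missing"
                    )
                obs = b if a_miss else a
                cells[(term, locus)] = frozenset({str(obs)})
                alphabets[locus].add(str(obs))
            else:
                cells[(term, locus)] = frozenset({str(a), str(b)})
                alphabets[locus] |= {str(a), str(b)}
    chars = [
        Character(locus, MICROSATELLITE, frozenset(alphabets[locus]))
        for locus in loci
    ]
    return CharacterMatrix(terminals, chars, cells)


def make_composite(
    matrix: CharacterMatrix, grouping: GroupingMap, level: str = "species"
) -> CharacterMatrix:
    """Collapse terminals into composite terminals at population/species level.

    Composite cells are the union of member state sets ignoring MISSING;
    a composite cell is MISSING only when every member is MISSING.  Groups
    must be non-empty (guaranteed because groups are induced by the matrix's
    own terminals).
    """
    if level not in ("population", "species"):
        raise ValueError(f"composite level must be population/species, not {level!r}")
    grouping.check_total(matrix.terminals)
    groups: dict = {}
    for t in matrix.terminals:
        groups.setdefault(grouping.unit_of(t, level), []).append(t)
    for unit, members in groups.items():
        if not members:
            raise ValueError(f"empty group {unit!r}")
    cells = {}
    for unit, members in groups.items():
        for c in matrix.characters:
            union: set = set()
            any_present = False
            for t in members:
                v = matrix.cell(t, c.id)
                if v is not MISSING:
                    any_present = True
                    union |= v
            cells[(unit, c.id)] = frozenset(union) if any_present else MISSING
    return CharacterMatrix(list(groups), matrix.characters, cells)


@dataclass
class CharacterClassification:
    """Per-character informativeness classes with summary counts."""

    classes: dict = field(default_factory=dict)  # char id -> class label
    n_constant: int = 0
    n_variable_uninformative: int = 0
    n_parsimony_informative: int = 0

    @property
    def n_variable(self) -> int:
        return self.n_variable_uninformative + self.n_parsimony_informative

    @property
    def n_total(self) -> int:
        return len(self.classes)


def classify_characters(matrix: CharacterMatrix) -> CharacterClassification:
    """Classify characters as constant / variable-uninformative / PI.

    Only unambiguous cells (single-state, non-missing) are tallied; a
    character is parsimony-informative iff at least two states each occur in
    at least two unambiguous cells, constant iff at most one state is
    observed, and variable-uninformative otherwise.
    """
    result = CharacterClassification()
    for c in matrix.characters:
        counts: dict = {}
        observed: set = set()
        for t in matrix.terminals:
            v = matrix.cell(t, c.id)
            if v is MISSING:
                continue
            observed |= v
            if len(v) == 1:
                s = next(iter(v))
                counts[s] = counts.get(s, 0) + 1
        unambiguous_states = {s for s, n in counts.items() if n >= 1}
        if len(unambiguous_states) <= 1:
            label = "constant"
            result.n_constant += 1
        elif sum(1 for n in counts.values() if n >= 2) >= 2:
            label = "parsimony-informative"
            result.n_parsimony_informative += 1
        else:
            label = "variable-uninformative"
            result.n_variable_uninformative += 1
        result.classes[c.id] = label
    return result
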