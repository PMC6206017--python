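"""Parsing and normalization of per-taxon biochemical reaction sets.

A taxon's metabolism is represented as a list of reactions, each with a set
of substrate metabolites, a set of product metabolites and a direction
(left-to-right, right-to-left, or reversible).  Before any network is
built, the raw export is normalized in four steps, applied in order:

1. transcode to UTF-8 (invalid bytes replaced),
2. drop byte-identical duplicate lines,
3. strip a leading stoichiometric coefficient from every metabolite name
   and apply the synonym map (e.g. ``NADP(H)`` -> ``NADPH``),
4. de-duplicate reactions identical in (substrates, products, direction).

Two input dialects are supported: a canonical tab-separated layout
(``reaction_id TAB substrates TAB products TAB direction`` with
``;``-separated sides and direction ``LR``/``RL``/``BOTH``) and free-text
equations (one per line, ``#`` comments), e.g. ``ATP + H2O => ADP + Pi``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class ReactionDirection(Enum):
    LEFT_TO_RIGHT = "LR"
    RIGHT_TO_LEFT = "RL"
    REVERSIBLE = "BOTH"


#: Default synonym map: the only standardization named for the source data.
DEFAULT_SYNONYMS: Mapping[str, str] = {"NADP(H)": "NADPH"}

# Leading stoichiometric coefficient: integer, decimal, fraction, or the
# symbolic "n", followed by whitespace.
_COEFF_RE = re.compile(r"^(?:\d+(?:\.\d+)?|\d+/\d+|n)\s+")

# Arrow tokens, longest first so "<=>" wins over "<=" and "=>".
_ARROWS: Sequence[tuple[str, ReactionDirection]] = (
    ("<=>", ReactionDirection.REVERSIBLE),
    ("⇔", ReactionDirection.REVERSIBLE),
    ("<=", ReactionDirection.RIGHT_TO_LEFT),
    ("⇐", ReactionDirection.RIGHT_TO_LEFT),
    ("=>", ReactionDirection.LEFT_TO_RIGHT),
    ("⇒", ReactionDirection.LEFT_TO_RIGHT),
    ("→", ReactionDirection.LEFT_TO_RIGHT),
)


class ReactionParseError(ValueError):
    """Raised for malformed reaction input; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class EmptyInputError(ReactionParseError):
    pass


def normalize_metabolite_name(
    raw: str, synonym_map: Mapping[str, str] | None = None
) -> str:
    """Normalize one metabolite name.

    Strips a leading stoichiometric coefficient, then applies the synonym
    map.  Raises :class:`ReactionParseError` if the name is empty after
    stripping.
    """
    if synonym_map is None:
        synonym_map = DEFAULT_SYNONYMS
    name = raw.strip()
    if not name:
        raise ReactionParseError(f"empty metabolite name in {raw!r}")
    name = _COEFF_RE.sub("", name)
    if not name:
        raise ReactionParseError(f"metabolite name {raw!r} empty after coefficient strip")
    return synonym_map.get(name, name)


def _normalize_side(
    names: Iterable[str], synonym_map: Mapping[str, str] | None
) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for raw in names:
        if not raw.strip():
            continue
        seen.setdefault(normalize_metabolite_name(raw, synonym_map), None)
    return tuple(seen)


@dataclass(frozen=True)
class ReactionRecord:
    """One biochemical reaction with normalized metabolite names.

    ``substrates`` and ``products`` are kept as ordered tuples of distinct
    names; identity (for de-duplication) compares them as unordered sets
    together with the direction.
    """

    reaction_id: str
    substrates: tuple[str, ...]
    products: tuple[str, ...]
    direction: ReactionDirection

    def __post_init__(self):
        if not self.substrates or not self.products:
            raise ReactionParseError(
                f"reaction {self.reaction_id!r}: both sides must be non-empty"
            )

    @property
    def key(self) -> tuple[frozenset, frozenset, ReactionDirection]:
        """Identity of the reaction irrespective of id and within-side order."""
        return (frozenset(self.substrates), frozenset(self.products), self.direction)

    @property
    def metabolites(self) -> frozenset[str]:
        return frozenset(self.substrates) | frozenset(self.products)


@dataclass
class ReactionSet:
    """A taxon's de-duplicated collection of reactions."""

    taxon_id: str
    records: list[ReactionRecord] = field(default_factory=list)

    @property
    def reaction_count(self) -> int:
        return len(self.records)

    @property
    def metabolites(self) -> frozenset[str]:
        out: set[str] = set()
        for r in self.records:
            out |= r.metabolites
        return frozenset(out)

    def deduplicated(self) -> "ReactionSet":
        seen: dict = {}
        for r in self.records:
            seen.setdefault(r.key, r)
        return ReactionSet(self.taxon_id, list(seen.values()))

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReactionSet):
            return NotImplemented
        return self.taxon_id == other.taxon_id and sorted(
            (r.key for r in self.records), key=repr
        ) == sorted((r.key for r in other.records), key=repr)


def equation_to_record(
    equation: str,
    reaction_id: str = "R1",
    synonym_map: Mapping[str, str] | None = None,
    line_number: int | None = None,
) -> ReactionRecord:
    """Parse a free-text equation like ``A + B => C`` into a record.

    Exactly one arrow token is required; sides are ``+``-separated.  A
    right-to-left arrow keeps the written sides unswapped and records
    direction ``RIGHT_TO_LEFT``.
    """
    hits = []
    for token, direction in _ARROWS:
        start = 0
        while (pos := equation.find(token, start)) != -1:
            # skip sub-tokens inside an already matched longer arrow
            if not any(h[0] <= pos < h[0] + len(h[1]) for h in hits):
                hits.append((pos, token, direction))
            start = pos + len(token)
    if len(hits) != 1:
        raise ReactionParseError(
            f"expected exactly one reaction arrow, found {len(hits)} in {equation!r}",
            line_number,
        )
    pos, token, direction = hits[0]
    left, right = equation[:pos], equation[pos + len(token):]
    substrates = _normalize_side(left.split("+"), synonym_map)
    products = _normalize_side(right.split("+"), synonym_map)
    if not substrates or not products:
        raise ReactionParseError(f"empty reaction side in {equation!r}", line_number)
    return ReactionRecord(reaction_id, substrates, products, direction)


def _parse_tsv_line(
    line: str, synonym_map: Mapping[str, str] | None, line_number: int
) -> ReactionRecord:
    parts = line.split("\t")
    if len(parts) != 4:
        raise ReactionParseError(
            f"expected 4 tab-separated fields, got {len(parts)}", line_number
        )
    rid, subs, prods, dircode = (p.strip() for p in parts)
    try:
        direction = ReactionDirection(dircode)
    except ValueError:
        raise ReactionParseError(f"unknown direction code {dircode!r}", line_number)
    substrates = _normalize_side(subs.split(";"), synonym_map)
    products = _normalize_side(prods.split(";"), synonym_map)
    if not substrates or not products:
        raise ReactionParseError("empty reaction side", line_number)
    return ReactionRecord(rid, substrates, products, direction)


def parse_reaction_lines(
    lines: Iterable[str],
    taxon_id: str,
    dialect: str = "tsv",
    synonym_map: Mapping[str, str] | None = None,
) -> ReactionSet:
    # step (ii): byte-identical duplicate lines dropped before parsing
    seen_lines: dict[str, None] = {}
    numbered: list[tuple[int, str]] = []
    for i, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if line in seen_lines:
            continue
        seen_lines[line] = None
        numbered.append((i, line))
    if not numbered:
        raise EmptyInputError("no reaction lines in input")

    records: list[ReactionRecord] = []
    for i, line in numbered:
        if dialect == "tsv":
            records.append(_parse_tsv_line(line, synonym_map, i))
        elif dialect == "equation":
            records.append(
                equation_to_record(line, f"RXN{i:05d}", synonym_map, line_number=i)
            )
        else:
            raise ValueError(f"unsupported dialect {dialect!r}")
    return ReactionSet(taxon_id, records).deduplicated()


def parse_reaction_file(
    path: str | Path,
    dialect: str = "tsv",
    taxon_id: str | None = None,
    synonym_map: Mapping[str, str] | None = None,
) -> ReactionSet:
    """Parse a reaction file into a normalized, de-duplicated ReactionSet.

    ``taxon_id`` defaults to the file stem.
    """
    path = Path(path)
    # step (i): transcode to UTF-8, replacing invalid bytes
    text = path.read_bytes().decode("utf-8", errors="replace")
    return parse_reaction_lines(
        text.splitlines(), taxon_id or path.stem, dialect, synonym_map
    )


def read_synonym_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (raw TAB canonical) synonym table; default entries kept."""
    out = dict(DEFAULT_SYNONYMS)
    for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ReactionParseError("expected 2 tab-separated columns", i)
        out[parts[0].strip()] = parts[1].strip()
    return out


def write_reaction_tsv(rs: ReactionSet, path: str | Path) -> None:
    """Serialize a ReactionSet in the canonical TSV dialect (round-trips)."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in rs.records:
            fh.write(
                f"{r.reaction_id}\t{';'.join(r.substrates)}\t"
                f"{';'.join(r.products)}\t{r.direction.value}\n"
            )
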