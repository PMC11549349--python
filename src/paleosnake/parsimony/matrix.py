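"""Character–taxon matrices for discrete morphology, with TNT and NEXUS I/O.

Cells are state sets (``frozenset`` of non-negative ints; more than one
state means an observed polymorphism) or one of two sentinels: ``MISSING``
(``?``) and ``INAPPLICABLE`` (``-``).  Both sentinels are optimized as full
ambiguity during tree-length computation, but the distinction is preserved
through every read/write round trip.

The TNT ``xread`` dialect is parsed natively (no installed library reads
TNT); NEXUS ``CHARACTERS``/``DATA`` blocks go through dendropy.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence, TextIO, Union

import dendropy

from paleosnake.errors import ParseError, ValidationError


class _Sentinel:
    def __init__(self, name: str, symbol: str):
        self.name, self.symbol = name, symbol

    def __repr__(self) -> str:
        return self.name


MISSING = _Sentinel("MISSING", "?")
INAPPLICABLE = _Sentinel("INAPPLICABLE", "-")

Cell = Union[frozenset, _Sentinel]

#: state symbols: 0-9 then A-Z for states 10-35
_SYMBOLS = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"


class Ordering(Enum):
    UNORDERED = "UNORDERED"
    ORDERED = "ORDERED"


def _state_to_symbol(s: int) -> str:
    if not 0 <= s < len(_SYMBOLS):
        raise ValidationError(f"state {s} out of symbol range")
    return _SYMBOLS[s]


def _symbol_to_state(ch: str) -> int:
    idx = _SYMBOLS.find(ch.upper())
    if idx < 0:
        raise ParseError(f"unknown state symbol {ch!r}")
    return idx


@dataclass
class CharacterMatrix:
    """Taxa x discrete characters, with per-character metadata."""

    taxa: list[str]
    cells: list[list[Cell]]
    ordering: list[Ordering] = field(default_factory=list)
    active: list[bool] = field(default_factory=list)
    weights: list[int] = field(default_factory=list)
    outgroup: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.taxa) != len(set(self.taxa)):
            dupes = {t for t in self.taxa if self.taxa.count(t) > 1}
            raise ValidationError(f"duplicate taxa: {sorted(dupes)}")
        if len(self.cells) != len(self.taxa):
            raise ValidationError("one row of cells per taxon required")
        n_char = len(self.cells[0]) if self.cells else 0
        for name, row in zip(self.taxa, self.cells):
            if len(row) != n_char:
                raise ValidationError(
                    f"taxon {name!r}: expected {n_char} cells, got {len(row)}"
                )
            for j, cell in enumerate(row):
                if isinstance(cell, frozenset):
                    if not cell or any(
                        not isinstance(s, int) or s < 0 for s in cell
                    ):
                        raise ValidationError(
                            f"taxon {name!r}, character {j}: invalid state set {cell}"
                        )
                elif cell is not MISSING and cell is not INAPPLICABLE:
                    raise ValidationError(
                        f"taxon {name!r}, character {j}: invalid cell {cell!r}"
                    )
        if not self.ordering:
            self.ordering = [Ordering.UNORDERED] * n_char
        if not self.active:
            self.active = [True] * n_char
        if not self.weights:
            self.weights = [1] * n_char
        for seq, label in (
            (self.ordering, "ordering"),
            (self.active, "active"),
            (self.weights, "weights"),
        ):
            if len(seq) != n_char:
                raise ValidationError(f"{label} must have one entry per character")
        if any(w < 1 for w in self.weights):
            raise ValidationError("weights must be positive integers")
        if self.outgroup is not None and self.outgroup not in self.taxa:
            raise ValidationError(f"outgroup {self.outgroup!r} not among taxa")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_char(self) -> int:
        return len(self.cells[0]) if self.cells else 0

    def observed_states(self, j: int) -> set[int]:
        out: set[int] = set()
        for row in self.cells:
            cell = row[j]
            if isinstance(cell, frozenset):
                out |= cell
        return out

    def subset_taxa(self, keep: Sequence[str]) -> "CharacterMatrix":
        index = {t: i for i, t in enumerate(self.taxa)}
        rows = [list(self.cells[index[t]]) for t in keep]
        return CharacterMatrix(
            taxa=list(keep),
            cells=rows,
            ordering=list(self.ordering),
            active=list(self.active),
            weights=list(self.weights),
            outgroup=self.outgroup if self.outgroup in keep else None,
        )


# ---------------------------------------------------------------------------
# TNT xread


def _open(source: Union[str, Path, TextIO]) -> TextIO:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    if isinstance(source, Path):
        return open(source, encoding="utf-8")
    if "\n" not in source and Path(source).exists():
        return open(source, encoding="utf-8")
    return io.StringIO(str(source))


def _parse_statestring(line: str, taxon: str) -> list[Cell]:
    cells: list[Cell] = []
    i = 0
    while i < len(line):
        ch = line[i]
        if ch == "?":
            cells.append(MISSING)
        elif ch == "-":
            cells.append(INAPPLICABLE)
        elif ch == "[" or ch == "(":
            close = "]" if ch == "[" else ")"
            end = line.find(close, i)
            if end < 0:
                raise ParseError(f"taxon {taxon!r}: unterminated {ch!r} group")
            group = line[i + 1 : end].replace(" ", "").replace(",", "")
            if not group:
                raise ParseError(f"taxon {taxon!r}: empty polymorphism group")
            cells.append(frozenset(_symbol_to_state(g) for g in group))
            i = end
        elif ch.isspace():
            pass
        else:
            cells.append(frozenset({_symbol_to_state(ch)}))
        i += 1
    return cells


def _apply_ccode(tokens: list[str], matrix: CharacterMatrix) -> None:
    """Apply a (simplified) TNT ccode command.

    Supported symbols: ``+`` ordered, ``-`` unordered, ``[`` active,
    ``]`` inactive, ``/N`` weight N; each applies to the following
    character indices or ``a.b`` ranges (0-based, TNT convention).
    """
    mode: Optional[str] = None
    weight = 1

    def apply(j: int) -> None:
        if not 0 <= j < matrix.n_char:
            raise ParseError(f"ccode: character index {j} out of range")
        if mode == "+":
            matrix.ordering[j] = Ordering.ORDERED
        elif mode == "-":
            matrix.ordering[j] = Ordering.UNORDERED
        elif mode == "[":
            matrix.active[j] = True
        elif mode == "]":
            matrix.active[j] = False
        elif mode == "/":
            matrix.weights[j] = weight

    for tok in tokens:
        if tok in "+-[]":
            mode = tok
        elif tok.startswith("/"):
            mode = "/"
            weight = int(tok[1:])
        elif "." in tok:
            a, b = tok.split(".")
            for j in range(int(a), int(b) + 1):
                apply(j)
        else:
            apply(int(tok))


def read_tnt(source: Union[str, Path, TextIO]) -> CharacterMatrix:
    """Parse a TNT ``xread`` block (plus optional ``ccode`` lines)."""
    fh = _open(source)
    text = fh.read()
    m = re.search(r"\bxread\b", text)
    if m is None:
        raise ParseError("no xread block found")
    rest = text[m.end():]
    # optional quoted title
    rest = re.sub(r"^\s*'[^']*'", "", rest, count=1)
    header = re.match(r"\s*(\d+)\s+(\d+)", rest)
    if header is None:
        raise ParseError("xread: expected 'nchar ntax' header")
    n_char, n_taxa = int(header.group(1)), int(header.group(2))
    body_end = rest.find(";", header.end())
    if body_end < 0:
        raise ParseError("xread: missing terminating ';'")
    body = rest[header.end():body_end]
    taxa: list[str] = []
    rows: list[list[Cell]] = []
    for line in body.splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise ParseError(f"xread: cannot parse row {line!r}")
        name, states = parts
        if name in taxa:
            raise ParseError(f"duplicate taxon {name!r}")
        cells = _parse_statestring(states, name)
        if len(cells) != n_char:
            raise ParseError(
                f"taxon {name!r}: {len(cells)} cells, expected {n_char} "
                f"(column {min(len(cells), n_char)})"
            )
        taxa.append(name)
        rows.append(cells)
    if len(taxa) != n_taxa:
        raise ParseError(f"expected {n_taxa} taxa, found {len(taxa)}")
    matrix = CharacterMatrix(taxa=taxa, cells=rows)
    for cmd in re.finditer(r"\bccode\b([^;]*);", text):
        _apply_ccode(cmd.group(1).split(), matrix)
    return matrix


def write_tnt(
    matrix: CharacterMatrix,
    path: Optional[Union[str, Path, TextIO]] = None,
    title: str = "",
) -> str:
    out = io.StringIO()
    out.write("xread\n")
    if title:
        out.write(f"'{title}'\n")
    out.write(f"{matrix.n_char} {matrix.n_taxa}\n")
    width = max(len(t) for t in matrix.taxa) + 2
    for name, row in zip(matrix.taxa, matrix.cells):
        symbols = []
        for cell in row:
            if cell is MISSING:
                symbols.append("?")
            elif cell is INAPPLICABLE:
                symbols.append("-")
            elif len(cell) == 1:
                symbols.append(_state_to_symbol(next(iter(cell))))
            else:
                symbols.append("[" + "".join(_state_to_symbol(s) for s in sorted(cell)) + "]")
        out.write(f"{name.replace(' ', '_'):<{width}}{''.join(symbols)}\n")
    out.write(";\n")
    ordered = [j for j, o in enumerate(matrix.ordering) if o is Ordering.ORDERED]
    inactive = [j for j, a in enumerate(matrix.active) if not a]
    weighted = [(j, w) for j, w in enumerate(matrix.weights) if w != 1]
    if ordered:
        out.write("ccode + " + " ".join(map(str, ordered)) + ";\n")
    if inactive:
        out.write("ccode ] " + " ".join(map(str, inactive)) + ";\n")
    for j, w in weighted:
        out.write(f"ccode /{w} {j};\n")
    out.write("proc /;\n")
    text = out.getvalue()
    if path is not None:
        if hasattr(path, "write"):
            path.write(text)  # type: ignore[union-attr]
        else:
            Path(path).write_text(text, encoding="utf-8")
    return text


# ---------------------------------------------------------------------------
# NEXUS (via dendropy)


def read_nexus(source: Union[str, Path, TextIO]) -> CharacterMatrix:
    """Read a NEXUS DATA/CHARACTERS block with standard (discrete) data."""
    fh = _open(source)
    text = fh.read()
    try:
        dm = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    except Exception as exc:
        raise ParseError(f"NEXUS parse failed: {exc}") from exc
    taxa: list[str] = []
    rows: list[list[Cell]] = []
    for taxon in dm:
        taxa.append(taxon.label)
        row: list[Cell] = []
        for state in dm[taxon]:
            denom = state.state_denomination
            if denom == dendropy.StateAlphabet.FUNDAMENTAL_STATE:
                if getattr(state, "is_gap_state", False) or state.symbol == "-":
                    row.append(INAPPLICABLE)
                else:
                    row.append(frozenset({_symbol_to_state(state.symbol)}))
            else:
                members = [
                    ms
                    for ms in (state.member_states or [])
                    if not getattr(ms, "is_gap_state", False) and ms.symbol != "-"
                ]
                if state.symbol == "?" or not members:
                    row.append(MISSING)
                else:
                    row.append(
                        frozenset(_symbol_to_state(ms.symbol) for ms in members)
                    )
        rows.append(row)
    if rows and any(len(r) != len(rows[0]) for r in rows):
        raise ParseError("NEXUS: unequal row lengths")
    return CharacterMatrix(taxa=taxa, cells=rows)


def write_nexus(
    matrix: CharacterMatrix, path: Optional[Union[str, Path, TextIO]] = None
) -> str:
    symbols = "".join(
        _SYMBOLS[s]
        for s in sorted(
            set().union(*(matrix.observed_states(j) for j in range(matrix.n_char)))
            or {0}
        )
    )
    out = io.StringIO()
    out.write("#NEXUS\n\nBEGIN DATA;\n")
    out.write(f"DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_char};\n")
    out.write(f'FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=? GAP=-;\n')
    out.write("MATRIX\n")
    width = max(len(t) for t in matrix.taxa) + 2
    for name, row in zip(matrix.taxa, matrix.cells):
        cells = []
        for cell in row:
            if cell is MISSING:
                cells.append("?")
            elif cell is INAPPLICABLE:
                cells.append("-")
            elif len(cell) == 1:
                cells.append(_state_to_symbol(next(iter(cell))))
            else:
                cells.append(
                    "(" + "".join(_state_to_symbol(s) for s in sorted(cell)) + ")"
                )
        out.write(f"{name.replace(' ', '_'):<{width}}{''.join(cells)}\n")
    out.write(";\nEND;\n")
    text = out.getvalue()
    if path is not None:
        if hasattr(path, "write"):
            path.write(text)  # type: ignore[union-attr]
        else:
            Path(path).write_text(text, encoding="utf-8")
    return text
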