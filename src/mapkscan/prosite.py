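"""PROSITE-syntax pattern engine.

Parses dash-separated PROSITE patterns — literals, ``[..]`` ambiguity sets,
``{..}`` exclusion sets, ``x`` wildcards and ``(i)`` / ``(i,j)`` repeat
counts — and scans protein sequences for matches, optionally tolerating a
bounded number of mismatched positions. Mismatches are only counted inside
fixed-length elements; variable-length elements (ranges with i < j) must
match exactly, which keeps the span enumeration well defined.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator

from .seqio import AMINO_ACIDS

_VALID_RESIDUES = frozenset(AMINO_ACIDS)


class PrositeSyntaxError(ValueError):
    """Raised on malformed PROSITE text; carries the character offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


@dataclass(frozen=True)
class Element:
    """One pattern element with a repeat count range.

    kind: 'literal', 'set', 'negated' or 'any' (the x wildcard).
    """

    kind: str
    residues: frozenset[str] = frozenset()
    min_count: int = 1
    max_count: int = 1

    @property
    def fixed_length(self) -> bool:
        return self.min_count == self.max_count

    def matches(self, ch: str) -> bool:
        if self.kind == "any":
            return True
        if self.kind == "negated":
            return ch not in self.residues
        return ch in self.residues

    def _body(self) -> str:
        if self.kind == "any":
            return "x"
        if self.kind == "literal":
            return next(iter(self.residues))
        inner = "".join(sorted(self.residues))
        return f"[{inner}]" if self.kind == "set" else f"{{{inner}}}"

    def __str__(self) -> str:
        body = self._body()
        if self.min_count == self.max_count == 1:
            return body
        if self.fixed_length:
            return f"{body}({self.min_count})"
        return f"{body}({self.min_count},{self.max_count})"


@dataclass(frozen=True)
class PrositePattern:
    elements: tuple[Element, ...]
    source_text: str = ""
    accession: str | None = None

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("pattern has no elements")

    def __str__(self) -> str:
        return "-".join(str(e) for e in self.elements)

    @property
    def min_length(self) -> int:
        return sum(e.min_count for e in self.elements)

    @property
    def max_length(self) -> int:
        return sum(e.max_count for e in self.elements)


@dataclass(frozen=True)
class PatternMatch:
    """A match span, 1-based inclusive, with its mismatch count."""

    start: int
    end: int
    mismatches: int

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def _parse_body(token: str, offset: int) -> tuple[str, frozenset[str], int]:
    """Parse the element body; returns (kind, residues, body length)."""
    if not token:
        raise PrositeSyntaxError("empty element", offset)
    ch = token[0]
    if ch in ("x", "X"):
        return "any", frozenset(), 1
    if ch in _VALID_RESIDUES:
        return "literal", frozenset(ch), 1
    if ch in "[{":
        close = "]" if ch == "[" else "}"
        end = token.find(close)
        if end < 0:
            raise PrositeSyntaxError(f"unbalanced {ch!r}", offset)
        inner = token[1:end]
        if not inner:
            raise PrositeSyntaxError("empty residue set", offset)
        for k, r in enumerate(inner):
            if r not in _VALID_RESIDUES:
                raise PrositeSyntaxError(
                    f"invalid residue {r!r} in set", offset + 1 + k
                )
        kind = "set" if ch == "[" else "negated"
        return kind, frozenset(inner), end + 1
    raise PrositeSyntaxError(f"unexpected character {ch!r}", offset)


def _parse_counts(token: str, offset: int) -> tuple[int, int]:
    if not token:
        return 1, 1
    if not (token.startswith("(") and token.endswith(")")):
        raise PrositeSyntaxError(f"trailing junk {token!r}", offset)
    inner = token[1:-1]
    parts = inner.split(",")
    try:
        nums = [int(p) for p in parts]
    except ValueError:
        raise PrositeSyntaxError(f"bad repeat count {inner!r}", offset) from None
    if len(nums) == 1:
        lo = hi = nums[0]
    elif len(nums) == 2:
        lo, hi = nums
    else:
        raise PrositeSyntaxError(f"bad repeat range {inner!r}", offset)
    if not (1 <= lo <= hi):
        raise PrositeSyntaxError(f"invalid repeat range ({lo},{hi})", offset)
    return lo, hi


def parse_prosite(text: str, accession: str | None = None) -> PrositePattern:
    """Parse PROSITE pattern text into a :class:`PrositePattern`.

    A trailing ``.`` terminator is tolerated. Raises
    :class:`PrositeSyntaxError` with the character offset on bad input.
    """
    stripped = text.strip()
    if stripped.endswith("."):
        stripped = stripped[:-1]
    if not stripped:
        raise PrositeSyntaxError("empty pattern", 0)
    elements: list[Element] = []
    offset = 0
    for token in stripped.split("-"):
        if not token:
            raise PrositeSyntaxError("empty element", offset)
        kind, residues, body_len = _parse_body(token, offset)
        lo, hi = _parse_counts(token[body_len:], offset + body_len)
        elements.append(Element(kind, residues, lo, hi))
        offset += len(token) + 1
    return PrositePattern(tuple(elements), source_text=text.strip(), accession=accession)


def _expansions(pattern: PrositePattern) -> Iterator[list[tuple[Element, bool]]]:
    """Yield per-position matcher lists, one per variable-length choice.

    Each position is ``(element, countable)``: mismatches may be charged only
    to countable positions (those arising from fixed-length elements).
    """
    choices = [range(e.min_count, e.max_count + 1) for e in pattern.elements]
    for counts in itertools.product(*choices):
        positions: list[tuple[Element, bool]] = []
        for e, k in zip(pattern.elements, counts):
            positions.extend([(e, e.fixed_length)] * k)
        yield positions


def match_pattern(
    pattern: PrositePattern, seq: str, max_mismatches: int = 0
) -> list[PatternMatch]:
    """All spans where ``pattern`` matches ``seq`` with <= ``max_mismatches``.

    Spans are 1-based inclusive, sorted by start then shorter first; each
    span is reported once with its best (minimum) mismatch count over the
    possible variable-length registrations.
    """
    seq = seq.upper()
    best: dict[tuple[int, int], int] = {}
    for positions in _expansions(pattern):
        length = len(positions)
        for start in range(len(seq) - length + 1):
            mismatches = 0
            ok = True
            for k, (el, countable) in enumerate(positions):
                if el.matches(seq[start + k]):
                    continue
                if not countable:
                    ok = False
                    break
                mismatches += 1
                if mismatches > max_mismatches:
                    ok = False
                    break
            if ok:
                span = (start + 1, start + length)
                if span not in best or mismatches < best[span]:
                    best[span] = mismatches
    return [
        PatternMatch(s, e, mm)
        for (s, e), mm in sorted(best.items(), key=lambda kv: (kv[0][0], kv[0][1]))
    ]
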