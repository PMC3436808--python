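"""Chemical sum formulas as element-count vectors.

A sum formula such as ``C6H12O6`` is represented as an :class:`ElementVector`,
an immutable mapping from IUPAC element symbols to positive integer atom
counts. These vectors are the columns of the mass matrix used to enforce
elemental mass balance of reactions: a reaction is balanced iff the weighted
sum of its metabolites' element vectors vanishes for every element.

The grammar is deliberately plain (Hill-style, no parentheses, no isotopes):
``symbol = capital letter + optional lowercase letter``, ``count = optional
positive integer (default 1)``. Underscore-decorated formulas as printed in
some tables (``C_6_H_10_O_5_``) are normalized on input.
"""

from __future__ import annotations

import re
from collections.abc import Iterator, Mapping

__all__ = ["ElementVector", "FormulaError", "parse_formula", "hill_formula"]

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised when a sum formula string cannot be parsed."""


class ElementVector(Mapping[str, int]):
    """Immutable element → atom-count mapping.

    Counts are integers ≥ 1; absent elements are simply not stored. Two
    vectors compare equal iff their mappings are equal.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int]):
        clean: dict[str, int] = {}
        for symbol, count in counts.items():
            if not isinstance(count, (int,)) or isinstance(count, bool):
                raise FormulaError(f"non-integer count {count!r} for element {symbol!r}")
            if count < 0:
                raise FormulaError(f"negative count {count} for element {symbol!r}")
            if count == 0:
                continue
            if not re.fullmatch(r"[A-Z][a-z]?", symbol):
                raise FormulaError(f"invalid element symbol {symbol!r}")
            clean[symbol] = count
        self._counts = dict(sorted(clean.items()))

    def __getitem__(self, symbol: str) -> int:
        return self._counts[symbol]

    def get(self, symbol: str, default: int = 0) -> int:
        return self._counts.get(symbol, default)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ElementVector):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self._counts == dict(other)
        return NotImplemented

    def __hash__(self) -> int:
        return hash(tuple(self._counts.items()))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ElementVector({hill_formula(self)!r})"

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(self._counts)


def parse_formula(text: str) -> ElementVector:
    """Parse a sum formula string into an :class:`ElementVector`.

    >>> dict(parse_formula("C6H10O5"))
    {'C': 6, 'H': 10, 'O': 5}

    Underscores decorating digit groups (``C_6_H_10_O_5_``) are stripped.
    Repeated element symbols accumulate (``CH3COOH`` would need parentheses
    anyway, but ``HOH`` parses to H2O). A zero count or a malformed token is
    rejected with a :class:`FormulaError` naming the offending piece.
    """
    if not isinstance(text, str):
        raise FormulaError(f"formula must be a string, got {type(text).__name__}")
    normalized = text.replace("_", "").strip()
    if not normalized:
        raise FormulaError(f"empty formula {text!r}")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(normalized):
        match = _TOKEN.match(normalized, pos)
        if match is None or match.start() != pos or not match.group(1):
            raise FormulaError(
                f"malformed formula {text!r}: unexpected token at {normalized[pos:]!r}"
            )
        symbol, digits = match.group(1), match.group(2)
        count = int(digits) if digits else 1
        if count == 0:
            raise FormulaError(f"zero count for element {symbol!r} in {text!r}")
        counts[symbol] = counts.get(symbol, 0) + count
        pos = match.end()
    return ElementVector(counts)


def hill_formula(vector: Mapping[str, int]) -> str:
    """Write an element vector as a canonical Hill-order formula string.

    Carbon first, then hydrogen, then all other elements alphabetically;
    without carbon, everything alphabetical. ``parse_formula(hill_formula(e))
    == e`` for every ElementVector.
    """
    counts = dict(vector)
    parts: list[str] = []

    def emit(symbol: str) -> None:
        count = counts.pop(symbol)
        parts.append(symbol if count == 1 else f"{symbol}{count}")

    if "C" in counts:
        emit("C")
        if "H" in counts:
            emit("H")
    for symbol in sorted(counts):
        emit(symbol)
    return "".join(parts)
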