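"""Roman numeral conversion and parsing, strict and lenient.

The *strict* form of a number is the unique subtractive-notation spelling
(4 = "IV", 9 = "IX", 40 = "XL", ...).  Clinical notes also contain additive
spellings such as "IIII" for 4; the *lenient* parser recovers a value from
these by summing symbol values while honouring subtractive pairs, and marks
them as not well formed.  The conversion domain is 1-3999, the boundary of
plain subtractive notation (no overline forms).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "RomanParseError",
    "RomanParseResult",
    "int_to_roman",
    "parse_roman",
    "is_roman_letters",
    "is_pure_additive",
]

_NUMERALS = (
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"),
    (100, "C"), (90, "XC"), (50, "L"), (40, "XL"),
    (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
)

SYMBOL_VALUES: dict[str, int] = {
    "i": 1, "v": 5, "x": 10, "l": 50, "c": 100, "d": 500, "m": 1000,
}


class RomanParseError(ValueError):
    """Raised for non-Roman characters, or non-canonical input in strict mode."""


@dataclass(frozen=True)
class RomanParseResult:
    """Outcome of parsing a Roman-numeral string.

    ``well_formed`` is true exactly when the input (case-insensitively)
    equals the strict subtractive spelling of ``value``.
    """

    value: int
    well_formed: bool
    text: str


def int_to_roman(n: int) -> str:
    """Strict subtractive-notation numeral for ``n``, uppercase; domain 1-3999."""
    if not isinstance(n, int) or isinstance(n, bool):
        raise TypeError(f"expected int, got {type(n).__name__}")
    if not 1 <= n <= 3999:
        raise ValueError(f"Roman numeral domain is 1-3999, got {n}")
    out: list[str] = []
    for value, symbol in _NUMERALS:
        while n >= value:
            out.append(symbol)
            n -= value
    return "".join(out)


def is_roman_letters(s: str) -> bool:
    """True iff ``s`` is non-empty and uses only Roman symbols (any case)."""
    t = s.lower()
    return bool(t) and all(ch in SYMBOL_VALUES for ch in t)


def is_pure_additive(s: str) -> bool:
    """True iff symbol values never increase left to right ("iiii", "viiii").

    Pure-additive strings carry no subtractive intent, which is what licenses
    reading a non-canonical string such as "IIII" as the number 4.
    """
    values = [SYMBOL_VALUES[ch] for ch in s.lower()]
    return bool(values) and all(a >= b for a, b in zip(values, values[1:]))


def _lenient_value(t: str) -> int:
    total = 0
    for i, ch in enumerate(t):
        v = SYMBOL_VALUES[ch]
        if i + 1 < len(t) and SYMBOL_VALUES[t[i + 1]] > v:
            total -= v
        else:
            total += v
    return total


def parse_roman(s: str, mode: str = "strict") -> RomanParseResult:
    """Parse a Roman numeral string.

    Parameters
    ----------
    s:
        Input string; letters from {I,V,X,L,C,D,M}, case-insensitive.
    mode:
        ``"strict"`` accepts only canonical subtractive forms and raises
        :class:`RomanParseError` otherwise; ``"lenient"`` additionally
        values additive forms (symbol sum with subtractive pairs honoured),
        setting ``well_formed=False`` for non-canonical input.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"mode must be 'strict' or 'lenient', got {mode!r}")
    t = s.strip().lower()
    if not t:
        raise RomanParseError("empty Roman numeral")
    if not is_roman_letters(t):
        raise RomanParseError(f"non-Roman characters in {s!r}")
    value = _lenient_value(t)
    well_formed = 1 <= value <= 3999 and int_to_roman(value).lower() == t
    if mode == "strict" and not well_formed:
        raise RomanParseError(f"{s!r} is not a canonical Roman numeral")
    return RomanParseResult(value=value, well_formed=well_formed, text=s)
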