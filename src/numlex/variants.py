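"""Generators for numeric lexical-variant surface forms in clinical text.

Twelve variant categories are covered: positive and negative integers,
fractions, dimensions, ranges/odds, dates (including invalid ones), Roman
numerals, medical classifications (type/stage/grade/class/phase/score),
ages (including implausible values), expressions of quantity,
ordering/ranking, and tuples.  Each generator emits
:class:`SurfaceForm` records carrying the surface text (always lowercase),
the category, a canonical value where one exists, and a validity flag:

* ``WELL_FORMED`` — an ordinary, correct spelling ("iv", "1st", "june 30");
* ``MALFORMED`` — a spelling error for which a well-formed counterpart with
  the same value exists ("iiii" for 4, "1rd" for "1st", "2ndary");
* ``INVALID_VALUE`` — well spelled but violating a domain rule
  ("june 31", "135 year old").

Deliberately generating the malformed and invalid forms is the point: they
occur in real notes, and a search or extraction pipeline that cannot
produce them cannot test whether it would miss them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache

from .index import tokenize
from .lexicons import load_decade_terms
from .roman import int_to_roman, is_pure_additive, parse_roman, RomanParseError
from .validity import (
    CalendarDate,
    LeapPolicy,
    MAX_PLAUSIBLE_AGE,
    MONTH_NAMES,
    is_plausible_age,
    is_valid_date,
)

__all__ = [
    "VariantCategory",
    "Validity",
    "SurfaceForm",
    "UnsupportedPhraseError",
    "int_to_roman",
    "generate_malformed_romans",
    "int_to_cardinal_words",
    "cardinal_words_to_int",
    "ordinal_suffix",
    "generate_ordinal_variants",
    "fraction_phrase",
    "dimension_phrase",
    "range_phrase",
    "negative_forms",
    "date_strings",
    "age_phrases",
    "decade_age_term",
    "tuple_terms",
    "classification_variants",
    "expand_phrase",
    "iter_all_generated_forms",
    "CLASSIFICATION_PREFIXES",
    "ORDINAL_WORDS",
    "ARY_WORDS",
    "ARY_HYBRIDS",
    "DENOMINATOR_SINGULAR",
    "DENOMINATOR_PLURAL",
    "TUPLE_BASE",
    "TUPLE_OFFSPRING",
]


class VariantCategory(str, Enum):
    """The twelve numeric lexical-variant categories."""

    POSITIVE_INTEGER = "positive_integer"
    NEGATIVE_INTEGER = "negative_integer"
    FRACTION = "fraction"
    DIMENSION = "dimension"
    RANGE_ODDS = "range_odds"
    DATE = "date"
    ROMAN_NUMERAL = "roman_numeral"
    MEDICAL_CLASSIFICATION = "medical_classification"
    AGE = "age"
    QUANTITY_EXPRESSION = "quantity_expression"
    ORDERING_RANKING = "ordering_ranking"
    TUPLE = "tuple"


class Validity(str, Enum):
    WELL_FORMED = "well_formed"
    MALFORMED = "malformed"
    INVALID_VALUE = "invalid_value"


@dataclass(frozen=True)
class SurfaceForm:
    """A numeric surface string with its category, canonical value, and validity.

    ``category`` and ``validity`` are ``None`` only for the "unclassified"
    marker returned by the detector for unrecognized input.
    """

    text: str
    category: VariantCategory | None
    canonical_value: int | tuple[int, int] | None = None
    validity: Validity | None = Validity.WELL_FORMED
    note: str = ""

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("surface text must be non-empty")
        if self.text != self.text.lower():
            raise ValueError(f"surface text must be lowercase: {self.text!r}")

    @property
    def is_classified(self) -> bool:
        return self.category is not None


class UnsupportedPhraseError(ValueError):
    """Raised by :func:`expand_phrase` for phrases with several numeric tokens."""


# ---------------------------------------------------------------------------
# cardinal words

_ONES = (
    "zero", "one", "two", "three", "four", "five", "six", "seven", "eight",
    "nine", "ten", "eleven", "twelve", "thirteen", "fourteen", "fifteen",
    "sixteen", "seventeen", "eighteen", "nineteen",
)
_TENS = (
    None, None, "twenty", "thirty", "forty", "fifty", "sixty", "seventy",
    "eighty", "ninety",
)


def int_to_cardinal_words(n: int) -> str:
    """Lowercase English cardinal words, hyphenated tens-units; domain 0-999.

    >>> int_to_cardinal_words(33)
    'thirty-three'
    """
    if not 0 <= n <= 999:
        raise ValueError(f"cardinal-word domain is 0-999, got {n}")
    if n < 20:
        return _ONES[n]
    if n < 100:
        tens, units = divmod(n, 10)
        word = _TENS[tens]
        return word if units == 0 else f"{word}-{_ONES[units]}"
    hundreds, rest = divmod(n, 100)
    word = f"{_ONES[hundreds]} hundred"
    return word if rest == 0 else f"{word} {int_to_cardinal_words(rest)}"


@lru_cache(maxsize=1)
def _cardinal_word_map() -> dict[str, int]:
    # keyed by token-normalized text so "thirty-three" and "thirty three" both resolve
    return {" ".join(tokenize(int_to_cardinal_words(n))): n for n in range(1000)}


def cardinal_words_to_int(text: str) -> int | None:
    """Inverse of :func:`int_to_cardinal_words`; ``None`` when unrecognized."""
    return _cardinal_word_map().get(" ".join(tokenize(text)))


def _word(n: int) -> str:
    return int_to_cardinal_words(n)


# ---------------------------------------------------------------------------
# Roman numerals

def generate_malformed_romans(
    n: int, max_run: int = 9, include_additive_v_forms: bool = False
) -> list[SurfaceForm]:
    """Additive-only (malformed) Roman spellings of ``n``.

    The default output is the pure repeated-I run ("iiii" for 4 up to
    "iiiiiiiii" for 9), the malformation actually observed in note text.
    ``include_additive_v_forms`` additionally emits V-plus-I-run additive
    spellings ("viiii" for 9) where they are not the strict form.  The
    strict subtractive spelling is never included.
    """
    if n < 4:
        raise ValueError(f"I-run malformations start at 4, got {n}")
    if max_run < n:
        raise ValueError(f"max_run ({max_run}) must be >= n ({n}) for a pure I-run")
    forms = [
        SurfaceForm("i" * n, VariantCategory.ROMAN_NUMERAL, n, Validity.MALFORMED,
                    note="additive I-run")
    ]
    if include_additive_v_forms and 5 < n <= 9:
        candidate = "v" + "i" * (n - 5)
        if candidate != int_to_roman(n).lower():
            forms.append(
                SurfaceForm(candidate, VariantCategory.ROMAN_NUMERAL, n, Validity.MALFORMED,
                            note="additive V+I form")
            )
    return forms


# ---------------------------------------------------------------------------
# ordinals

ORDINAL_WORDS: dict[int, str] = {
    1: "first", 2: "second", 3: "third", 4: "fourth", 5: "fifth",
    6: "sixth", 7: "seventh", 8: "eighth", 9: "ninth",
}
ARY_WORDS: dict[int, str] = {
    1: "primary", 2: "secondary", 3: "tertiary", 4: "quaternary",
    5: "quinary", 6: "senary", 7: "septenary",
}
# digit hybrids of the "-ary" series attested in note text
ARY_HYBRIDS: dict[int, tuple[str, ...]] = {
    1: ("1ary",),
    2: ("2ndary", "2ary"),
    3: ("3rdary", "3ary"),
    4: ("4ary",),
}
_SUFFIXES = ("st", "nd", "rd", "th")


def ordinal_suffix(n: int) -> str:
    """The correct two-letter ordinal ending (st/nd/rd/th) for ``n`` >= 1.

    Determined by the last two digits: any number whose tens digit is 1
    (10-19, 110-119, ...) takes "th"; otherwise the last digit decides.
    """
    if n < 1:
        raise ValueError(f"ordinal domain starts at 1, got {n}")
    if (n // 10) % 10 == 1:
        return "th"
    return {1: "st", 2: "nd", 3: "rd"}.get(n % 10, "th")


def generate_ordinal_variants(n: int) -> list[SurfaceForm]:
    """All ordering/ranking surface forms for a single digit 1-9.

    Emits the digit with all four suffixes (one well formed, three
    malformed), the ordinal word, the adverbial "-ly" word and its digit
    hybrid ("firstly" / "1stly"), and the "-ary" series with its attested
    digit hybrids ("primary" / "1ary", "secondary" / "2ndary").
    """
    if not 1 <= n <= 9:
        raise ValueError(f"ordinal-variant domain is 1-9, got {n}")
    cat = VariantCategory.ORDERING_RANKING
    correct = ordinal_suffix(n)
    forms = [
        SurfaceForm(f"{n}{suffix}", cat, n,
                    Validity.WELL_FORMED if suffix == correct else Validity.MALFORMED)
        for suffix in _SUFFIXES
    ]
    word = ORDINAL_WORDS[n]
    forms.append(SurfaceForm(word, cat, n, Validity.WELL_FORMED))
    forms.append(SurfaceForm(f"{word}ly", cat, n, Validity.WELL_FORMED))
    forms.append(SurfaceForm(f"{n}{correct}ly", cat, n, Validity.MALFORMED,
                             note="digit hybrid of -ly adverb"))
    if n in ARY_WORDS:
        forms.append(SurfaceForm(ARY_WORDS[n], cat, n, Validity.WELL_FORMED))
    for hybrid in ARY_HYBRIDS.get(n, ()):
        forms.append(SurfaceForm(hybrid, cat, n, Validity.MALFORMED,
                                 note="digit hybrid of -ary word"))
    return forms


# ---------------------------------------------------------------------------
# fractions, dimensions, ranges, negatives

DENOMINATOR_SINGULAR: dict[int, str] = {
    2: "half", 3: "third", 4: "fourth", 5: "fifth", 6: "sixth",
    7: "seventh", 8: "eighth", 9: "ninth", 10: "tenth",
}
DENOMINATOR_PLURAL: dict[int, str] = {
    den: ("halves" if den == 2 else word + "s") for den, word in DENOMINATOR_SINGULAR.items()
}


def fraction_phrase(numerator: int, denominator: int, include_errors: bool = False) -> list[SurfaceForm]:
    """Spelled-out fraction phrases with singular/plural agreement.

    "one third", "two thirds", "one half"; with ``include_errors`` also the
    plural-mismatch form ("one thirds") flagged as malformed.
    """
    if not 1 <= numerator <= 10:
        raise ValueError(f"numerator domain is 1-10, got {numerator}")
    if not 2 <= denominator <= 10:
        raise ValueError(f"denominator domain is 2-10, got {denominator}")
    num_word = _word(numerator)
    correct = DENOMINATOR_SINGULAR[denominator] if numerator == 1 else DENOMINATOR_PLURAL[denominator]
    wrong = DENOMINATOR_PLURAL[denominator] if numerator == 1 else DENOMINATOR_SINGULAR[denominator]
    forms = [
        SurfaceForm(f"{num_word} {correct}", VariantCategory.FRACTION,
                    (numerator, denominator), Validity.WELL_FORMED)
    ]
    if include_errors:
        forms.append(
            SurfaceForm(f"{num_word} {wrong}", VariantCategory.FRACTION,
                        (numerator, denominator), Validity.MALFORMED,
                        note="plural disagreement")
        )
    return forms


def dimension_phrase(a: int, b: int) -> str:
    """Spelled-out dimension, e.g. ``dimension_phrase(2, 4) == "two by four"``."""
    if not (1 <= a <= 10 and 1 <= b <= 10):
        raise ValueError(f"dimension domain is 1-10, got ({a}, {b})")
    return f"{_word(a)} by {_word(b)}"


def range_phrase(a: int, b: int) -> str:
    """Spelled-out range or odds, e.g. "one to three"; a == b is permitted."""
    if not (1 <= a <= 10 and 1 <= b <= 10):
        raise ValueError(f"range domain is 1-10, got ({a}, {b})")
    return f"{_word(a)} to {_word(b)}"


def negative_forms(n: int) -> list[SurfaceForm]:
    """The four spelled/mixed negative-integer forms for 1 <= n <= 10.

    "minus five", "minus 5", "negative five", "negative 5".
    """
    if not 1 <= n <= 10:
        raise ValueError(f"negative-form domain is 1-10, got {n}")
    word = _word(n)
    return [
        SurfaceForm(f"{sign} {body}", VariantCategory.NEGATIVE_INTEGER, -n, Validity.WELL_FORMED)
        for sign in ("minus", "negative")
        for body in (word, str(n))
    ]


# ---------------------------------------------------------------------------
# dates and ages

def date_strings(
    month: int,
    day: int,
    with_suffix: bool = False,
    leap_policy: LeapPolicy = LeapPolicy.LENIENT_FEB29,
) -> list[SurfaceForm]:
    """Month-name date strings, optionally with an ordinal suffix.

    Validity follows the calendar: "january 31" is well formed, "june 31"
    and "january 35" carry ``INVALID_VALUE``.  The suffix form uses the
    correct suffix for the day ("june 31st").
    """
    if not 1 <= month <= 12:
        raise ValueError(f"month must be 1-12, got {month}")
    if not 1 <= day <= 39:
        raise ValueError(f"day domain is 1-39, got {day}")
    validity = (
        Validity.WELL_FORMED
        if is_valid_date(CalendarDate(month, day, leap_policy))
        else Validity.INVALID_VALUE
    )
    name = MONTH_NAMES[month - 1]
    forms = [SurfaceForm(f"{name} {day}", VariantCategory.DATE, (month, day), validity)]
    if with_suffix:
        forms.append(
            SurfaceForm(f"{name} {day}{ordinal_suffix(day)}", VariantCategory.DATE,
                        (month, day), validity)
        )
    return forms


def age_phrases(age: int, bound: int = MAX_PLAUSIBLE_AGE) -> list[SurfaceForm]:
    """"<age> year old" phrases; ages above the bound carry ``INVALID_VALUE``."""
    if not 0 <= age <= 999:
        raise ValueError(f"age domain is 0-999, got {age}")
    validity = Validity.WELL_FORMED if is_plausible_age(age, bound) else Validity.INVALID_VALUE
    return [
        SurfaceForm(f"{age} year old", VariantCategory.AGE, age, validity),
        SurfaceForm(f"{age}-year-old", VariantCategory.AGE, age, validity),
    ]


def decade_age_term(age: int) -> str | None:
    """The decade word whose bracket contains ``age``, or ``None``.

    Prefers the most specific bracket (supercentenarian over centenarian at
    110 and above).  Below 50 no bracket applies and ``None`` is returned.
    """
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    best: str | None = None
    best_low = -1
    for term in load_decade_terms():
        high = term.age_high if term.age_high is not None else float("inf")
        if term.age_low <= age <= high and term.age_low > best_low:
            best, best_low = term.word, term.age_low
    return best


# ---------------------------------------------------------------------------
# tuples

TUPLE_BASE: dict[int, str] = {
    1: "single", 2: "double", 3: "triple", 4: "quadruple",
    5: "quintuple", 6: "sextuple", 7: "septuple", 8: "octuple",
}
TUPLE_OFFSPRING: dict[int, str] = {
    1: "singleton", 2: "twins", 3: "triplets", 4: "quadruplets",
    5: "quintuplets", 6: "sextuplets", 7: "septuplets", 8: "octuplets",
}


def tuple_terms(n: int) -> list[SurfaceForm]:
    """Tuple vocabulary for ``n``: base word, -ing/-ed/-s forms, offspring term.

    The offspring term for 2 is "twins", not a regular formation.
    """
    if not 1 <= n <= 8:
        raise ValueError(f"tuple domain is 1-8, got {n}")
    base = TUPLE_BASE[n]
    stem = base[:-1]  # every base ends in 'e'
    words = [base, f"{stem}ing", f"{stem}ed", f"{base}s", TUPLE_OFFSPRING[n]]
    return [
        SurfaceForm(word, VariantCategory.TUPLE, n, Validity.WELL_FORMED) for word in words
    ]


# ---------------------------------------------------------------------------
# medical classifications

CLASSIFICATION_PREFIXES = ("type", "phase", "grade", "stage", "class", "score")
_COMPOUND_LETTERS = "abcdefghij"


def classification_variants(prefix: str, n: int, letter: str | None = None) -> list[SurfaceForm]:
    """Arabic/Roman classification spellings: "type 2", "type ii", "stage 3b".

    With ``letter`` (a-j), letter-suffixed compounds are emitted both with
    and without the prefix word ("stage 3b", "3b", "iiib").  A roman+letter
    compound is skipped when the concatenation is itself a readable Roman
    numeral (e.g. "iii" + "i" would spell "iiii"), since that string reads
    as a malformed numeral rather than a classification.
    """
    if prefix not in CLASSIFICATION_PREFIXES:
        raise ValueError(f"prefix must be one of {CLASSIFICATION_PREFIXES}, got {prefix!r}")
    if not 1 <= n <= 5:
        raise ValueError(f"classification domain is 1-5, got {n}")
    if letter is not None and (len(letter) != 1 or letter.lower() not in _COMPOUND_LETTERS):
        raise ValueError(f"letter must be a single character a-j, got {letter!r}")
    cat = VariantCategory.MEDICAL_CLASSIFICATION
    arabic, roman = str(n), int_to_roman(n).lower()
    note = f"prefix={prefix}"
    forms = [
        SurfaceForm(f"{prefix} {arabic}", cat, n, Validity.WELL_FORMED, note=note),
        SurfaceForm(f"{prefix} {roman}", cat, n, Validity.WELL_FORMED, note=note),
    ]
    if letter is not None:
        lt = letter.lower()
        compounds = [f"{arabic}{lt}"]
        roman_compound = f"{roman}{lt}"
        if not _reads_as_roman(roman_compound):
            compounds.append(roman_compound)
        for compound in compounds:
            forms.append(SurfaceForm(f"{prefix} {compound}", cat, n, Validity.WELL_FORMED,
                                     note=f"{note} letter={lt}"))
            forms.append(SurfaceForm(compound, cat, n, Validity.WELL_FORMED,
                                     note=f"letter={lt}"))
    return forms


def _reads_as_roman(token: str) -> bool:
    """Strict numerals and pure-additive strings read as Roman, not compounds."""
    try:
        result = parse_roman(token, mode="lenient")
    except RomanParseError:
        return False
    return result.well_formed or is_pure_additive(token)


# ---------------------------------------------------------------------------
# query expansion

def iter_all_generated_forms():
    """Every :class:`SurfaceForm` each generator can emit, over its full domain.

    Yields plain-string generator outputs (Roman numerals, cardinal words,
    dimension and range phrases) wrapped as well-formed forms too, so the
    iterator enumerates the complete generation surface.  Used to check the
    generator/detector duality: the classifier must recover category,
    canonical value, and validity for every item.
    """
    for n in range(1, 4000):
        yield SurfaceForm(int_to_roman(n).lower(), VariantCategory.ROMAN_NUMERAL, n,
                          Validity.WELL_FORMED)
    for n in range(4, 10):
        yield from generate_malformed_romans(n, include_additive_v_forms=True)
    for n in range(1000):
        yield SurfaceForm(int_to_cardinal_words(n), VariantCategory.POSITIVE_INTEGER, n,
                          Validity.WELL_FORMED)
    for n in range(1, 10):
        yield from generate_ordinal_variants(n)
    for num in range(1, 11):
        for den in range(2, 11):
            yield from fraction_phrase(num, den, include_errors=True)
    for a in range(1, 11):
        for b in range(1, 11):
            yield SurfaceForm(dimension_phrase(a, b), VariantCategory.DIMENSION, (a, b),
                              Validity.WELL_FORMED)
            yield SurfaceForm(range_phrase(a, b), VariantCategory.RANGE_ODDS, (a, b),
                              Validity.WELL_FORMED)
    for n in range(1, 11):
        yield from negative_forms(n)
    for month in range(1, 13):
        for day in range(1, 40):
            for with_suffix in (False, True):
                yield from date_strings(month, day, with_suffix=with_suffix)
    for age in range(1000):
        yield from age_phrases(age)
    for n in range(1, 9):
        yield from tuple_terms(n)
    for prefix in CLASSIFICATION_PREFIXES:
        for n in range(1, 6):
            for letter in (None, *_COMPOUND_LETTERS):
                yield from classification_variants(prefix, n, letter)


_DIGITS_RE = re.compile(r"^\d+$")


def _numeric_token_value(token: str) -> int | None:
    """Value of a numeric query token (digits, strict Roman, or cardinal word), 1-39."""
    if _DIGITS_RE.match(token):
        value = int(token)
        return value if 1 <= value <= 39 else None
    try:
        result = parse_roman(token, mode="strict")
        if 1 <= result.value <= 39:
            return result.value
    except RomanParseError:
        pass
    value = _cardinal_word_map().get(token)
    if value is not None and 1 <= value <= 39:
        return value
    return None


def expand_phrase(phrase: str) -> set[str]:
    """Expand a search phrase across Arabic, Roman, and word numeral spellings.

    The phrase may contain at most one numeric token (an Arabic digit
    string, a strict Roman numeral, or a cardinal word, each valued 1-39);
    that token is substituted with all three spellings.  Phrases without a
    numeric token expand to themselves; several numeric tokens raise
    :class:`UnsupportedPhraseError`.

    >>> sorted(expand_phrase("stage 3 chronic kidney disease"))[2]
    'stage three chronic kidney disease'
    """
    tokens = tokenize(phrase)
    numeric = [(i, v) for i, t in enumerate(tokens) if (v := _numeric_token_value(t)) is not None]
    if len(numeric) > 1:
        raise UnsupportedPhraseError(
            f"phrase {phrase!r} contains {len(numeric)} numeric tokens; "
            "expansion supports at most one"
        )
    expanded = {phrase}
    if numeric:
        pos, value = numeric[0]
        for spelling in (str(value), int_to_roman(value).lower(), int_to_cardinal_words(value)):
            substituted = list(tokens)
            substituted[pos] = spelling
            expanded.add(" ".join(substituted))
    return expanded
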