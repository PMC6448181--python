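"""Detection: map surface strings back to categories, values, and validity.

This is the inverse of the generators in :mod:`numlex.variants`: every
surface form a generator can emit is classified back to the same category,
canonical value, and validity flag (the generator/detector duality that the
test suite enforces).  Classification is *total* — unrecognized input
yields an unclassified marker, never an exception — and tries readings in
a fixed priority: date > age > classification > roman > ordinal >
cardinal/word forms > tuple > quantity lexicons.

Two refinements inside that priority are worth knowing about:

* A token made of Roman letters that is either a strict numeral or a
  pure-additive string ("ii", "iiii") is read as a Roman numeral, never as
  a roman+letter classification compound — otherwise "iiii" would parse as
  the compound iii+I instead of the malformed numeral 4.
* Document annotation marks numeric spans for normalization, so a
  classification prefix word ("type" in "type ii diabetes") is treated as
  context: the span covers the numeral itself.

Ambiguity is flagged, not resolved: single-letter Roman tokens and
lexicon-listed collisions with common abbreviations ("iv" intravenous,
"va", "if") are annotated ``ambiguous=True`` and left unnormalized.
Contextual word-sense disambiguation is out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

from .index import NoteDocument, tokenize
from .lexicons import (
    load_ambiguous_tokens,
    load_decade_terms,
    load_informal_quantities,
    load_scale_words,
)
from .roman import (
    RomanParseError,
    RomanParseResult,
    SYMBOL_VALUES,
    is_pure_additive,
    is_roman_letters,
    parse_roman,
)
from .validity import (
    CalendarDate,
    LeapPolicy,
    MAX_PLAUSIBLE_AGE,
    MONTH_NUMBER,
    is_plausible_age,
    is_valid_date,
)
from .variants import (
    ARY_WORDS,
    CLASSIFICATION_PREFIXES,
    DENOMINATOR_PLURAL,
    DENOMINATOR_SINGULAR,
    ORDINAL_WORDS,
    SurfaceForm,
    TUPLE_BASE,
    TUPLE_OFFSPRING,
    Validity,
    VariantCategory,
    cardinal_words_to_int,
    ordinal_suffix,
)

__all__ = [
    "AnnotatedSpan",
    "parse_roman",
    "RomanParseResult",
    "RomanParseError",
    "is_valid_date",
    "is_plausible_age",
    "check_ordinal",
    "classify_surface",
    "annotate_document",
    "annotate_corpus",
    "normalize_document",
    "write_annotations",
]


def check_ordinal(number_text: str, suffix: str) -> bool:
    """True iff ``suffix`` is the correct ordinal ending for the digit string."""
    if suffix not in ("st", "nd", "rd", "th"):
        raise ValueError(f"suffix must be one of st/nd/rd/th, got {suffix!r}")
    if not number_text.isdigit():
        raise ValueError(f"number_text must be a digit string, got {number_text!r}")
    return suffix == ordinal_suffix(int(number_text))


# ---------------------------------------------------------------------------
# classification of single surface strings

_ORDINAL_DIGIT_RE = re.compile(r"^(\d+)(st|nd|rd|th)$")
_ORDINAL_LY_RE = re.compile(r"^(\d+)(st|nd|rd|th)ly$")
_ORDINAL_ARY_RE = re.compile(r"^(\d+)(st|nd|rd|th)?ary$")
_DAY_RE = re.compile(r"^(\d{1,2})(st|nd|rd|th)?$")
_COMPOUND_RE = re.compile(r"^(iv|i{1,3}|v|[1-5])([a-j])$")
_DIGITS_RE = re.compile(r"^\d+$")

_ORDINAL_WORD_TO_N = {w: n for n, w in ORDINAL_WORDS.items()}
_ORDINAL_LY_TO_N = {w + "ly": n for n, w in ORDINAL_WORDS.items()}
_ARY_WORD_TO_N = {w: n for n, w in ARY_WORDS.items()}
_DENOM_TO_N = {
    **{w: (n, "singular") for n, w in DENOMINATOR_SINGULAR.items()},
    **{w: (n, "plural") for n, w in DENOMINATOR_PLURAL.items()},
}


@lru_cache(maxsize=1)
def _tuple_form_map() -> dict[str, int]:
    forms: dict[str, int] = {}
    for n, base in TUPLE_BASE.items():
        stem = base[:-1]
        for word in (base, f"{stem}ing", f"{stem}ed", f"{base}s", TUPLE_OFFSPRING[n]):
            forms[word] = n
    return forms


@lru_cache(maxsize=1)
def _decade_word_map() -> dict[str, tuple[int, int | None]]:
    return {t.word: (t.age_low, t.age_high) for t in load_decade_terms()}


@lru_cache(maxsize=1)
def _scale_word_forms() -> dict[str, str]:
    """Singular and plural scale words mapped to their lexicon headword."""
    forms: dict[str, str] = {}
    for word in load_scale_words():
        forms[word] = word
        if not word.endswith("s") and word != "infinity":
            forms[word + "s"] = word
    return forms


def _unclassified(text: str) -> SurfaceForm:
    return SurfaceForm(text=text, category=None, canonical_value=None,
                       validity=None, note="unclassified")


def _classification_number(token: str) -> int | None:
    """Value 1-5 of a classification number token (digit, strict roman, compound)."""
    if token in ("1", "2", "3", "4", "5"):
        return int(token)
    if token in ("i", "ii", "iii", "iv", "v"):
        return parse_roman(token, mode="strict").value
    compound = _classification_compound(token)
    return compound


def _classification_compound(token: str) -> int | None:
    """Value of a number+letter compound ("3b", "iiib", "va"), else ``None``.

    Tokens that read as Roman numerals outright (strict or pure-additive)
    are excluded so that "ii" and "iiii" stay numerals.
    """
    if is_roman_letters(token) and (_is_strict_roman(token) or is_pure_additive(token)):
        return None
    m = _COMPOUND_RE.match(token)
    if not m:
        return None
    head = m.group(1)
    if head.isdigit():
        return int(head)
    return parse_roman(head, mode="strict").value


def _is_strict_roman(token: str) -> bool:
    try:
        return parse_roman(token, mode="strict").well_formed
    except RomanParseError:
        return False


def _try_date(tokens: Sequence[str], leap_policy: LeapPolicy) -> SurfaceForm | None:
    if len(tokens) != 2 or tokens[0] not in MONTH_NUMBER:
        return None
    m = _DAY_RE.match(tokens[1])
    if not m:
        return None
    day = int(m.group(1))
    if not 1 <= day <= 39:
        return None
    month = MONTH_NUMBER[tokens[0]]
    text = " ".join(tokens)
    if not is_valid_date(CalendarDate(month, day, leap_policy)):
        validity = Validity.INVALID_VALUE
    elif m.group(2) is not None and m.group(2) != ordinal_suffix(day):
        validity = Validity.MALFORMED
    else:
        validity = Validity.WELL_FORMED
    return SurfaceForm(text, VariantCategory.DATE, (month, day), validity)


def _try_age(tokens: Sequence[str], age_bound: int) -> SurfaceForm | None:
    if (
        len(tokens) == 3
        and _DIGITS_RE.match(tokens[0])
        and tokens[1] in ("year", "years")
        and tokens[2] == "old"
    ):
        age = int(tokens[0])
        validity = Validity.WELL_FORMED if is_plausible_age(age, age_bound) else Validity.INVALID_VALUE
        return SurfaceForm(" ".join(tokens), VariantCategory.AGE, age, validity)
    if len(tokens) == 1 and tokens[0] in _decade_word_map():
        low, high = _decade_word_map()[tokens[0]]
        bracket = f"{low}-{high}" if high is not None else f"{low}+"
        return SurfaceForm(tokens[0], VariantCategory.AGE, None, Validity.WELL_FORMED,
                           note=f"age bracket {bracket}")
    return None


def _try_classification(tokens: Sequence[str], for_annotation: bool) -> SurfaceForm | None:
    if len(tokens) == 2 and tokens[0] in CLASSIFICATION_PREFIXES and not for_annotation:
        value = _classification_number(tokens[1])
        if value is not None:
            return SurfaceForm(" ".join(tokens), VariantCategory.MEDICAL_CLASSIFICATION,
                               value, Validity.WELL_FORMED, note=f"prefix={tokens[0]}")
    if len(tokens) == 1:
        value = _classification_compound(tokens[0])
        if value is not None:
            return SurfaceForm(tokens[0], VariantCategory.MEDICAL_CLASSIFICATION,
                               value, Validity.WELL_FORMED, note="letter compound")
    return None


def _try_roman(tokens: Sequence[str]) -> SurfaceForm | None:
    if len(tokens) != 1 or not is_roman_letters(tokens[0]):
        return None
    token = tokens[0]
    if _is_strict_roman(token):
        return SurfaceForm(token, VariantCategory.ROMAN_NUMERAL,
                           parse_roman(token, mode="lenient").value, Validity.WELL_FORMED)
    if is_pure_additive(token):
        value = parse_roman(token, mode="lenient").value
        if 1 <= value <= 3999:
            return SurfaceForm(token, VariantCategory.ROMAN_NUMERAL, value,
                               Validity.MALFORMED, note="additive form")
    return None


def _try_ordinal(tokens: Sequence[str]) -> SurfaceForm | None:
    if len(tokens) != 1:
        return None
    token = tokens[0]
    cat = VariantCategory.ORDERING_RANKING
    m = _ORDINAL_DIGIT_RE.match(token)
    if m:
        value = int(m.group(1))
        validity = Validity.WELL_FORMED if m.group(2) == ordinal_suffix(value) else Validity.MALFORMED
        return SurfaceForm(token, cat, value, validity)
    m = _ORDINAL_LY_RE.match(token)
    if m:
        return SurfaceForm(token, cat, int(m.group(1)), Validity.MALFORMED,
                           note="digit hybrid of -ly adverb")
    m = _ORDINAL_ARY_RE.match(token)
    if m:
        return SurfaceForm(token, cat, int(m.group(1)), Validity.MALFORMED,
                           note="digit hybrid of -ary word")
    if token in _ORDINAL_WORD_TO_N:
        return SurfaceForm(token, cat, _ORDINAL_WORD_TO_N[token], Validity.WELL_FORMED)
    if token in _ORDINAL_LY_TO_N:
        return SurfaceForm(token, cat, _ORDINAL_LY_TO_N[token], Validity.WELL_FORMED)
    if token in _ARY_WORD_TO_N:
        return SurfaceForm(token, cat, _ARY_WORD_TO_N[token], Validity.WELL_FORMED)
    return None


def _cardinal_value(tokens: Sequence[str]) -> int | None:
    if len(tokens) == 1 and _DIGITS_RE.match(tokens[0]):
        return int(tokens[0])
    return cardinal_words_to_int(" ".join(tokens))


def _word_cardinal(token: str) -> int | None:
    """Value of a spelled cardinal word ("three"), digits excluded."""
    if _DIGITS_RE.match(token):
        return None
    return cardinal_words_to_int(token)


def _try_number_forms(tokens: Sequence[str]) -> SurfaceForm | None:
    text = " ".join(tokens)
    if len(tokens) >= 2 and tokens[0] in ("minus", "negative"):
        value = _cardinal_value(tokens[1:])
        if value is not None:
            return SurfaceForm(text, VariantCategory.NEGATIVE_INTEGER, -value,
                               Validity.WELL_FORMED)
    if len(tokens) == 3 and tokens[1] in ("by", "to"):
        a, b = _word_cardinal(tokens[0]), _word_cardinal(tokens[2])
        if a is not None and b is not None:
            cat = VariantCategory.DIMENSION if tokens[1] == "by" else VariantCategory.RANGE_ODDS
            return SurfaceForm(text, cat, (a, b), Validity.WELL_FORMED)
    if len(tokens) == 2 and tokens[1] in _DENOM_TO_N:
        num = _word_cardinal(tokens[0])
        if num is not None and 1 <= num <= 10:
            den, grammatical_number = _DENOM_TO_N[tokens[1]]
            agrees = (grammatical_number == "singular") == (num == 1)
            return SurfaceForm(text, VariantCategory.FRACTION, (num, den),
                               Validity.WELL_FORMED if agrees else Validity.MALFORMED,
                               note="" if agrees else "plural disagreement")
    value = _cardinal_value(tokens)
    if value is not None:
        return SurfaceForm(text, VariantCategory.POSITIVE_INTEGER, value, Validity.WELL_FORMED)
    return None


def _try_tuple(tokens: Sequence[str]) -> SurfaceForm | None:
    if len(tokens) == 1 and tokens[0] in _tuple_form_map():
        return SurfaceForm(tokens[0], VariantCategory.TUPLE, _tuple_form_map()[tokens[0]],
                           Validity.WELL_FORMED)
    return None


def _try_quantity(tokens: Sequence[str]) -> SurfaceForm | None:
    text = " ".join(tokens)
    cat = VariantCategory.QUANTITY_EXPRESSION
    scale_forms = _scale_word_forms()
    if text in load_informal_quantities():
        return SurfaceForm(text, cat, None, Validity.WELL_FORMED, note="informal quantity")
    if all(token in scale_forms for token in tokens):
        heads = [scale_forms[t] for t in tokens]
        entry = load_scale_words()[heads[-1]]
        note = f"10^{entry.exponent}" if entry.exponent is not None else (entry.special or "")
        return SurfaceForm(text, cat, None, Validity.WELL_FORMED, note=note)
    if len(tokens) == 2 and tokens[0] in ("minus", "negative") and tokens[1] in scale_forms:
        return SurfaceForm(text, cat, None, Validity.WELL_FORMED, note="negated magnitude")
    return None


def _classify_tokens(
    tokens: Sequence[str],
    *,
    age_bound: int = MAX_PLAUSIBLE_AGE,
    leap_policy: LeapPolicy = LeapPolicy.LENIENT_FEB29,
    for_annotation: bool = False,
) -> SurfaceForm | None:
    """Fixed-priority dispatch over readings; ``None`` when nothing matches."""
    return (
        _try_date(tokens, leap_policy)
        or _try_age(tokens, age_bound)
        or _try_classification(tokens, for_annotation)
        or _try_roman(tokens)
        or _try_ordinal(tokens)
        or _try_number_forms(tokens)
        or _try_tuple(tokens)
        or _try_quantity(tokens)
    )


def classify_surface(
    s: str,
    *,
    age_bound: int = MAX_PLAUSIBLE_AGE,
    leap_policy: LeapPolicy = LeapPolicy.LENIENT_FEB29,
) -> SurfaceForm:
    """Classify an arbitrary surface string; total (never raises on content).

    Unrecognized input yields the unclassified marker (``category is None``).

    >>> classify_surface("january 35").validity
    <Validity.INVALID_VALUE: 'invalid_value'>
    >>> classify_surface("xv").canonical_value
    15
    """
    if not s:
        raise ValueError("surface string must be non-empty")
    tokens = tokenize(s)
    if not tokens:
        return _unclassified(s.lower())
    result = _classify_tokens(tokens, age_bound=age_bound, leap_policy=leap_policy)
    return result if result is not None else _unclassified(" ".join(tokens))


# ---------------------------------------------------------------------------
# document annotation

@dataclass(frozen=True)
class AnnotatedSpan:
    """A numeric span over a token sequence; ``end_token`` is exclusive."""

    start_token: int
    end_token: int
    surface: str
    category: VariantCategory
    canonical_value: int | tuple[int, int] | None
    validity: Validity
    ambiguous: bool


_MAX_SPAN = 4  # longest multi-token pattern (informal quantity phrases)


def _is_ambiguous_token(token: str) -> bool:
    return token in load_ambiguous_tokens() or (len(token) == 1 and token in SYMBOL_VALUES)


def annotate_document(
    tokens: Sequence[str],
    *,
    age_bound: int = MAX_PLAUSIBLE_AGE,
    leap_policy: LeapPolicy = LeapPolicy.LENIENT_FEB29,
) -> list[AnnotatedSpan]:
    """Non-overlapping numeric spans over a tokenized document.

    Longest match wins, scanning left to right.  Classification prefix
    words are treated as context (the span in "type ii diabetes" covers
    "ii"), and ambiguous tokens are flagged rather than skipped.
    """
    spans: list[AnnotatedSpan] = []
    i = 0
    n = len(tokens)
    while i < n:
        matched = False
        for width in range(min(_MAX_SPAN, n - i), 0, -1):
            window = tokens[i : i + width]
            form = _classify_tokens(
                window, age_bound=age_bound, leap_policy=leap_policy, for_annotation=True
            )
            if form is not None:
                ambiguous = width == 1 and _is_ambiguous_token(window[0])
                spans.append(
                    AnnotatedSpan(i, i + width, form.text, form.category,
                                  form.canonical_value, form.validity, ambiguous)
                )
                i += width
                matched = True
                break
        if not matched:
            i += 1
    return spans


def normalize_document(tokens: Sequence[str]) -> list[str]:
    """Rewrite unambiguous integer-valued spans to Arabic digits.

    Ambiguous spans and invalid values are left untouched — normalizing
    "iv fluids" to "4 fluids" or "june 31" to a real date would destroy
    information.  Spans whose canonical value is not a single integer
    (fractions, dates, dimensions) are also left as-is.
    """
    out: list[str] = []
    i = 0
    spans = {span.start_token: span for span in annotate_document(tokens)}
    while i < len(tokens):
        span = spans.get(i)
        if (
            span is not None
            and not span.ambiguous
            and span.validity in (Validity.WELL_FORMED, Validity.MALFORMED)
            and isinstance(span.canonical_value, int)
        ):
            out.append(str(span.canonical_value))
            i = span.end_token
        else:
            out.append(tokens[i])
            i += 1
    return out


def annotate_corpus(
    docs: Iterable[NoteDocument],
    *,
    age_bound: int = MAX_PLAUSIBLE_AGE,
    leap_policy: LeapPolicy = LeapPolicy.LENIENT_FEB29,
) -> list[tuple[str, AnnotatedSpan]]:
    """Annotate every document; returns ``(doc_id, span)`` pairs in order."""
    results: list[tuple[str, AnnotatedSpan]] = []
    for doc in docs:
        for span in annotate_document(
            tokenize(doc.text), age_bound=age_bound, leap_policy=leap_policy
        ):
            results.append((doc.doc_id, span))
    return results


def write_annotations(annotations: Iterable[tuple[str, AnnotatedSpan]], path: str | Path) -> None:
    """Write annotations as delimited text (one span per line)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("doc_id\tstart\tend\tsurface\tcategory\tcanonical_value\tvalidity\tambiguous\n")
        for doc_id, span in annotations:
            value = (
                "" if span.canonical_value is None
                else ("/".join(map(str, span.canonical_value))
                      if isinstance(span.canonical_value, tuple) else str(span.canonical_value))
            )
            fh.write(
                f"{doc_id}\t{span.start_token}\t{span.end_token}\t{span.surface}\t"
                f"{span.category.value}\t{value}\t{span.validity.value}\t"
                f"{'true' if span.ambiguous else 'false'}\n"
            )
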