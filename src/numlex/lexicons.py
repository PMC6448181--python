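"""Plain-text lexicon resources and their loaders.

Four lexicons ship with the package, one entry per line, user-extensible by
passing a path to the loader instead of relying on the bundled copy:

* ``scale_words.tsv`` — short-scale magnitude words (hundred .. undecillion)
  with their power of ten, plus the named curiosities googol and googolplex
  and the non-finite "infinity".
* ``decade_terms.tsv`` — single words denoting an age bracket
  (septuagenarian = 70-79, ...), open-ended brackets marked ``inf``.
* ``informal_quantities.txt`` — informal/imprecise quantity phrases
  ("gobs of", "too many to count").
* ``ambiguous_tokens.txt`` — tokens that double as numeric surface forms and
  common abbreviations or words (IV intravenous, VA Veterans Affairs, ...);
  annotation flags these instead of normalizing them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources as importlib_resources
from pathlib import Path

__all__ = [
    "ScaleWordEntry",
    "DecadeAgeTerm",
    "load_scale_words",
    "load_decade_terms",
    "load_informal_quantities",
    "load_ambiguous_tokens",
]

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def _norm(text: str) -> str:
    return " ".join(_TOKEN_RE.findall(text.lower()))


@dataclass(frozen=True)
class ScaleWordEntry:
    """A magnitude word and the power of ten it denotes.

    ``exponent`` is ``None`` for entries that denote no finite power of ten;
    ``special`` then says why ("infinite" for infinity, "non_representable"
    for googolplex, whose exponent 10**100 is not a useful integer).
    """

    word: str
    exponent: int | None
    special: str | None = None


@dataclass(frozen=True)
class DecadeAgeTerm:
    """A word for an age bracket; ``age_high`` is ``None`` when open-ended."""

    word: str
    age_low: int
    age_high: int | None


def _read_lines(name: str, path: str | Path | None) -> list[str]:
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
    else:
        text = (
            importlib_resources.files("numlex.resources").joinpath(name).read_text(encoding="utf-8")
        )
    return [line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")]


def _cacheable(fn):
    """Cache only the bundled-resource (path=None) call."""
    cache: dict[str, object] = {}

    def wrapper(path: str | Path | None = None):
        if path is None:
            if "value" not in cache:
                cache["value"] = fn(None)
            return cache["value"]
        return fn(path)

    wrapper.__wrapped__ = fn  # type: ignore[attr-defined]
    wrapper.__doc__ = fn.__doc__
    wrapper.__name__ = fn.__name__
    return wrapper


@_cacheable
def load_scale_words(path: str | Path | None = None) -> dict[str, ScaleWordEntry]:
    """Load the magnitude-word lexicon as ``{word: ScaleWordEntry}``."""
    entries: dict[str, ScaleWordEntry] = {}
    for line in _read_lines("scale_words.tsv", path):
        word, _, raw = line.partition("\t")
        word = word.strip()
        raw = raw.strip()
        if raw == "infinite":
            entry = ScaleWordEntry(word, None, "infinite")
        elif raw == "non_representable":
            entry = ScaleWordEntry(word, None, "non_representable")
        else:
            entry = ScaleWordEntry(word, int(raw))
        entries[word] = entry
    return entries


@_cacheable
def load_decade_terms(path: str | Path | None = None) -> tuple[DecadeAgeTerm, ...]:
    """Load the decade-age lexicon in file order."""
    terms: list[DecadeAgeTerm] = []
    for line in _read_lines("decade_terms.tsv", path):
        word, low, high = line.split("\t")
        terms.append(
            DecadeAgeTerm(word.strip(), int(low), None if high.strip() == "inf" else int(high))
        )
    return tuple(terms)


@_cacheable
def load_informal_quantities(path: str | Path | None = None) -> frozenset[str]:
    """Informal quantity phrases, token-normalized (lowercase, punctuation-split)."""
    return frozenset(_norm(line) for line in _read_lines("informal_quantities.txt", path))


@_cacheable
def load_ambiguous_tokens(path: str | Path | None = None) -> frozenset[str]:
    """Tokens flagged as ambiguous between numeric and non-numeric senses."""
    return frozenset(line.lower() for line in _read_lines("ambiguous_tokens.txt", path))
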