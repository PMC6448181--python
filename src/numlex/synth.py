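"""Seeded generator of clinical-note-like corpora with ground-truth injection.

Real note corpora are inaccessible, so pipeline behaviour is validated on
synthetic ones whose every relevant property is known exactly.  The
generator emulates the statistical structure the overlap analysis assumes:

* patients carry several notes (truncated-geometric note count);
* a concept phrase ("stage <N> chronic kidney disease") is injected for a
  configurable fraction of patients, and each mention independently uses
  the Arabic, Roman, or spelled-word numeral variant with configured
  probabilities — patients with several notes can therefore acquire both
  spellings, which is what produces the "both" column of the overlap
  counts;
* rare error forms (malformed Romans, bad ordinal suffixes, invalid dates,
  implausible ages) are injected as standalone sentences at configured
  rates.

Every injection is recorded in a :class:`GroundTruthLedger`, and the filler
vocabulary excludes every token of every configured phrase, so a phrase can
occur in a document only where the ledger says it does.  A post-generation
scan verifies this by construction-independent token matching.

The generator draws everything from one seeded pseudo-random stream, so a
fixed seed reproduces the corpus byte for byte.  The defaults describe no
real institution; they are synthetic study conditions, not estimates.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .index import NoteDocument, tokenize
from .roman import int_to_roman
from .variants import int_to_cardinal_words

__all__ = [
    "InjectionSpec",
    "GroundTruthLedger",
    "ConfigError",
    "VARIANTS",
    "ERROR_KINDS",
    "generate_corpus",
    "ledger_counts",
    "verify_ledger",
    "demo_specs",
    "load_corpus_config",
]

VARIANTS = ("arabic", "roman", "word")
ERROR_KINDS = ("malformed_roman", "bad_ordinal", "invalid_date", "implausible_age")

_ERROR_SURFACES: dict[str, tuple[str, ...]] = {
    "malformed_roman": tuple("i" * k for k in range(4, 10)),
    "bad_ordinal": ("1rd", "1nd", "2th", "3st", "2rd", "3nd"),
    "invalid_date": ("june 31", "february 30", "september 38", "april 31", "january 35"),
    "implausible_age": ("135 year old", "150 year old", "123 year old", "200 year old"),
}

# Clinical-flavoured filler vocabulary.  Words that collide with phrase
# tokens, numeral spellings, month names, or numeric lexicons are filtered
# out again at run time against the actual specs.
_FILLER_WORDS = (
    "patient", "presented", "clinic", "for", "routine", "followup", "visit",
    "review", "of", "symptoms", "denies", "fever", "chills", "nausea",
    "vomiting", "pain", "reports", "feeling", "well", "overall", "exam",
    "unremarkable", "lungs", "clear", "heart", "rhythm", "abdomen",
    "soft", "nontender", "extremities", "warm", "without", "edema", "labs",
    "reviewed", "stable", "continue", "current", "medications", "plan",
    "monitor", "discussed", "with", "the", "family", "will", "return", "as",
    "needed", "sleep", "appetite", "gait", "steady", "alert", "oriented",
    "skin", "rash", "noted", "blood", "pressure", "controlled", "home",
    "regimen", "unchanged", "tolerating", "diet", "bowel", "habits",
    "breath", "sounds", "bilaterally", "neuro", "grossly", "counseled",
    "regarding", "activity", "hydration", "rest", "improving", "slowly",
    "since", "encounter", "tolerated", "procedure", "recovery",
    "uneventful", "vitals", "afebrile", "comfortable", "resting",
    "ambulating", "assistance", "wound", "healing", "margins", "dressing",
    "changed", "daily", "follow", "up", "scheduled", "next", "week",
    "telephone", "nurse", "pharmacy", "refill", "sent", "records",
    "requested", "outside", "facility", "imaging", "pending", "results",
)


class ConfigError(ValueError):
    """Raised for invalid generator configuration."""


@dataclass(frozen=True)
class InjectionSpec:
    """One concept to inject: a phrase template with a numeric slot.

    ``template`` contains the slot marker ``<N>``; ``value`` fills it as an
    Arabic digit, a strict lowercase Roman numeral, or a cardinal word
    according to the per-mention ``variant_probs`` (which must sum to 1).
    ``prevalence`` is the fraction of patients carrying the concept, and
    each note of a carrier mentions it with probability ``mention_prob``.
    ``error_rates`` inject standalone error sentences per note per kind.
    """

    template: str
    value: int
    variant_probs: Mapping[str, float]
    prevalence: float = 0.1
    mention_prob: float = 1.0
    error_rates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "<N>" not in self.template:
            raise ConfigError(f"template {self.template!r} lacks the <N> slot")
        if set(self.variant_probs) - set(VARIANTS):
            raise ConfigError(f"unknown variant keys in {dict(self.variant_probs)}")
        probs = [float(self.variant_probs.get(v, 0.0)) for v in VARIANTS]
        if any(p < 0 or p > 1 for p in probs):
            raise ConfigError("variant probabilities must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigError(f"variant probabilities must sum to 1, got {sum(probs)}")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ConfigError(f"prevalence must lie in [0, 1], got {self.prevalence}")
        if not 0.0 <= self.mention_prob <= 1.0:
            raise ConfigError(f"mention_prob must lie in [0, 1], got {self.mention_prob}")
        for kind, rate in self.error_rates.items():
            if kind not in ERROR_KINDS:
                raise ConfigError(f"unknown error kind {kind!r}")
            if not 0.0 <= float(rate) <= 1.0:
                raise ConfigError(f"error rate for {kind!r} must lie in [0, 1], got {rate}")

    def phrase(self, variant: str) -> str:
        """The concrete phrase for one variant spelling."""
        if variant == "arabic":
            surface = str(self.value)
        elif variant == "roman":
            surface = int_to_roman(self.value).lower()
        elif variant == "word":
            surface = int_to_cardinal_words(self.value)
        else:
            raise ValueError(f"unknown variant {variant!r}")
        return self.template.replace("<N>", surface)

    @property
    def concept(self) -> str:
        """Ledger key for this concept."""
        return self.template


class GroundTruthLedger:
    """Record of exactly which phrases and error forms went into which notes."""

    def __init__(self) -> None:
        # concept -> patient_id -> variant -> sorted-insert list of doc_ids
        self.injections: dict[str, dict[str, dict[str, list[str]]]] = {}
        # kind -> list of (doc_id, surface)
        self.errors: dict[str, list[tuple[str, str]]] = {}

    def record(self, concept: str, patient_id: str, variant: str, doc_id: str) -> None:
        self.injections.setdefault(concept, {}).setdefault(patient_id, {}).setdefault(
            variant, []
        ).append(doc_id)

    def record_error(self, kind: str, doc_id: str, surface: str) -> None:
        self.errors.setdefault(kind, []).append((doc_id, surface))

    @property
    def concepts(self) -> list[str]:
        return sorted(self.injections)

    def patients(self, concept: str) -> set[str]:
        return set(self.injections.get(concept, {}))

    def variant_mention_counts(self, concept: str) -> dict[str, int]:
        """Total mentions per variant for a concept (one per injected note)."""
        counts = {v: 0 for v in VARIANTS}
        for per_patient in self.injections.get(concept, {}).values():
            for variant, docs in per_patient.items():
                counts[variant] += len(docs)
        return counts

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format": "numlex-ledger",
            "version": 1,
            "injections": self.injections,
            "errors": {kind: [list(pair) for pair in pairs] for kind, pairs in self.errors.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthLedger":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if payload.get("format") != "numlex-ledger":
            raise ValueError(f"{path}: not a numlex ledger file")
        ledger = cls()
        ledger.injections = payload["injections"]
        ledger.errors = {
            kind: [tuple(pair) for pair in pairs] for kind, pairs in payload["errors"].items()
        }
        return ledger


def ledger_counts(ledger: GroundTruthLedger, concept: str) -> tuple[int, int, int]:
    """Patient counts (arabic-only, both, roman-only) for a ledgered concept.

    Patients whose only mentions used the spelled-word variant appear in
    none of the three counts, mirroring a two-phrase Arabic/Roman search.
    """
    if concept not in ledger.injections:
        raise KeyError(f"concept {concept!r} not in ledger")
    b = d = e = 0
    for per_patient in ledger.injections[concept].values():
        has_arabic = bool(per_patient.get("arabic"))
        has_roman = bool(per_patient.get("roman"))
        if has_arabic and has_roman:
            d += 1
        elif has_arabic:
            b += 1
        elif has_roman:
            e += 1
    return b, d, e


def _truncated_geometric(rng: random.Random, mean: float, maximum: int) -> int:
    """Geometric note count (support 1..maximum, tail mass lumped at maximum)."""
    if mean <= 1.0:
        return 1
    q = 1.0 - 1.0 / mean
    u = rng.random()
    k = 1 + int(math.log(1.0 - u) / math.log(q))
    return min(max(k, 1), maximum)


def _forbidden_tokens(specs: Sequence[InjectionSpec]) -> set[str]:
    forbidden: set[str] = set()
    for spec in specs:
        for variant in VARIANTS:
            forbidden.update(tokenize(spec.phrase(variant)))
    for surfaces in _ERROR_SURFACES.values():
        for surface in surfaces:
            forbidden.update(tokenize(surface))
    return forbidden


def generate_corpus(
    specs: Sequence[InjectionSpec],
    n_patients: int,
    seed: int,
    *,
    notes_mean: float = 3.0,
    notes_max: int = 20,
    sentences_per_note: tuple[int, int] = (2, 4),
    words_per_sentence: tuple[int, int] = (5, 10),
    verify: bool = True,
) -> tuple[list[NoteDocument], GroundTruthLedger]:
    """Generate a synthetic corpus and its ground-truth ledger.

    Deterministic for a fixed seed.  With ``verify`` (the default) every
    document is re-scanned after generation and the occurrence count of
    every configured phrase and error surface is checked against the
    ledger, guaranteeing filler hygiene.
    """
    if n_patients < 1:
        raise ConfigError(f"n_patients must be >= 1, got {n_patients}")
    if notes_max < 1:
        raise ConfigError(f"notes_max must be >= 1, got {notes_max}")
    rng = random.Random(seed)
    forbidden = _forbidden_tokens(specs)
    vocabulary = [w for w in _FILLER_WORDS if w not in forbidden]
    if len(vocabulary) < 20:
        raise ConfigError("filler vocabulary exhausted by phrase-token exclusions")

    variant_names = list(VARIANTS)
    docs: list[NoteDocument] = []
    ledger = GroundTruthLedger()
    for p in range(n_patients):
        patient_id = f"p{p:05d}"
        n_notes = _truncated_geometric(rng, notes_mean, notes_max)
        carries = {spec.concept: rng.random() < spec.prevalence for spec in specs}
        for j in range(n_notes):
            doc_id = f"{patient_id}-n{j:02d}"
            n_sentences = rng.randint(*sentences_per_note)
            sentences = [
                " ".join(rng.choices(vocabulary, k=rng.randint(*words_per_sentence)))
                for _ in range(n_sentences)
            ]
            for spec in specs:
                if carries[spec.concept] and rng.random() < spec.mention_prob:
                    weights = [float(spec.variant_probs.get(v, 0.0)) for v in variant_names]
                    variant = rng.choices(variant_names, weights=weights)[0]
                    sentences.insert(rng.randint(0, len(sentences)), spec.phrase(variant))
                    ledger.record(spec.concept, patient_id, variant, doc_id)
                for kind, rate in spec.error_rates.items():
                    if rng.random() < float(rate):
                        surface = rng.choice(_ERROR_SURFACES[kind])
                        sentences.insert(rng.randint(0, len(sentences)), surface)
                        ledger.record_error(kind, doc_id, surface)
            docs.append(NoteDocument(doc_id, patient_id, ". ".join(sentences) + "."))
    if verify:
        verify_ledger(docs, ledger, specs)
    return docs, ledger


def _count_occurrences(tokens: Sequence[str], phrase_tokens: Sequence[str]) -> int:
    first = phrase_tokens[0]
    width = len(phrase_tokens)
    count = 0
    for i, token in enumerate(tokens):
        if token == first and list(tokens[i : i + width]) == list(phrase_tokens):
            count += 1
    return count


def verify_ledger(
    docs: Iterable[NoteDocument],
    ledger: GroundTruthLedger,
    specs: Sequence[InjectionSpec],
) -> None:
    """Scan every document and check phrase/error occurrences against the ledger.

    Raises ``RuntimeError`` on any discrepancy: a ledgered injection that is
    not present verbatim, or an accidental occurrence the ledger does not
    know about.
    """
    expected: dict[str, dict[tuple[str, ...], int]] = {}
    for spec in specs:
        for variant in VARIANTS:
            phrase_tokens = tuple(tokenize(spec.phrase(variant)))
            for per_patient in ledger.injections.get(spec.concept, {}).values():
                for doc_id in per_patient.get(variant, []):
                    expected.setdefault(doc_id, {}).setdefault(phrase_tokens, 0)
                    expected[doc_id][phrase_tokens] += 1
    for kind, pairs in ledger.errors.items():
        for doc_id, surface in pairs:
            surface_tokens = tuple(tokenize(surface))
            expected.setdefault(doc_id, {}).setdefault(surface_tokens, 0)
            expected[doc_id][surface_tokens] += 1

    probes: set[tuple[str, ...]] = set()
    for spec in specs:
        for variant in VARIANTS:
            probes.add(tuple(tokenize(spec.phrase(variant))))
    for surfaces in _ERROR_SURFACES.values():
        for surface in surfaces:
            probes.add(tuple(tokenize(surface)))

    for doc in docs:
        tokens = tokenize(doc.text)
        for probe in probes:
            found = _count_occurrences(tokens, probe)
            want = expected.get(doc.doc_id, {}).get(probe, 0)
            if found != want:
                raise RuntimeError(
                    f"ledger mismatch in {doc.doc_id}: phrase {' '.join(probe)!r} "
                    f"occurs {found} time(s), ledger says {want}"
                )


def demo_specs() -> list[InjectionSpec]:
    """The packaged demonstration study conditions (synthetic, not estimates)."""
    return [
        InjectionSpec(
            template="stage <N> chronic kidney disease",
            value=3,
            variant_probs={"arabic": 0.60, "roman": 0.35, "word": 0.05},
            prevalence=0.15,
            error_rates={"invalid_date": 0.01, "implausible_age": 0.005},
        ),
        InjectionSpec(
            template="type <N> diabetes mellitus",
            value=2,
            variant_probs={"arabic": 0.75, "roman": 0.20, "word": 0.05},
            prevalence=0.25,
            error_rates={"malformed_roman": 0.01, "bad_ordinal": 0.01},
        ),
        InjectionSpec(
            template="grade <N> anaplastic astrocytoma",
            value=3,
            variant_probs={"arabic": 0.40, "roman": 0.55, "word": 0.05},
            prevalence=0.05,
        ),
    ]


def load_corpus_config(path: str | Path) -> dict:
    """Load a YAML generator configuration.

    Returns a dict with keys ``specs`` (list of :class:`InjectionSpec`),
    ``n_patients``, ``seed``, and optional ``notes_mean`` / ``notes_max``.
    """
    try:
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        specs = [
            InjectionSpec(
                template=s["template"],
                value=int(s["value"]),
                variant_probs=s["variant_probs"],
                prevalence=float(s.get("prevalence", 0.1)),
                mention_prob=float(s.get("mention_prob", 1.0)),
                error_rates=s.get("error_rates", {}),
            )
            for s in raw["specs"]
        ]
        config = {
            "specs": specs,
            "n_patients": int(raw["n_patients"]),
            "seed": int(raw["seed"]),
            "notes_mean": float(raw.get("notes_mean", 3.0)),
            "notes_max": int(raw.get("notes_max", 20)),
        }
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"{path}: missing or malformed field: {exc}") from exc
    if config["n_patients"] < 1:
        raise ConfigError(f"{path}: n_patients must be >= 1")
    return config
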