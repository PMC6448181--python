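"""Tokenization, positional inverted indexing, and exact phrase search.

The tokenizer contract is deliberately simple and fully specified: text is
lowercased, and tokens are maximal runs of ASCII letters and digits.  Mixed
alphanumeric runs ("t2dm", "3b") stay single tokens; every other character
— including hyphens, colons, and apostrophes — separates tokens and is
discarded.  This reproduces the distinctions the variant analysis relies on
("DM2" vs "DM 2", "thirty-three" splitting into two tokens) without any
linguistic analysis.

Stop words are indexed like any other token: in clinical text many of them
double as medical acronyms (IS incentive spirometry, OR operating room), so
dropping them would silently change counts.

Phrase search is exact consecutive-position matching, case-insensitive, and
counts each document once regardless of how often the phrase occurs in it.
Patient-level counting aggregates document hits through the doc→patient map.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

__all__ = [
    "NoteDocument",
    "InvertedIndex",
    "tokenize",
    "build_index",
    "phrase_search",
    "patient_set",
    "read_corpus",
    "write_corpus",
]

_TOKEN_RE = re.compile(r"[a-z0-9]+")

_SNAPSHOT_FORMAT = "numlex-index"
_SNAPSHOT_VERSION = 1


def tokenize(text: str) -> list[str]:
    """Lowercase tokens as maximal runs of letters and digits.

    >>> tokenize("Mallampati score: IV")
    ['mallampati', 'score', 'iv']
    >>> tokenize("thirty-three")
    ['thirty', 'three']
    """
    return _TOKEN_RE.findall(text.lower())


@dataclass(frozen=True)
class NoteDocument:
    """One clinical note: a unique document id, its patient id, and free text."""

    doc_id: str
    patient_id: str
    text: str


class InvertedIndex:
    """Token → postings-with-positions map over a note corpus.

    Postings are stored per token as ``{doc_id: [positions]}`` with strictly
    increasing positions; the index also keeps the doc→patient map so that
    search hits can be counted at the distinct-patient level.
    """

    def __init__(self) -> None:
        self._postings: dict[str, dict[str, list[int]]] = {}
        self._doc_patient: dict[str, str] = {}

    # -- construction ------------------------------------------------------

    @classmethod
    def from_documents(cls, docs: Iterable[NoteDocument]) -> "InvertedIndex":
        index = cls()
        for doc in docs:
            index.add_document(doc)
        return index

    def add_document(self, doc: NoteDocument) -> None:
        if doc.doc_id in self._doc_patient:
            raise ValueError(f"duplicate doc_id {doc.doc_id!r}")
        self._doc_patient[doc.doc_id] = doc.patient_id
        for pos, token in enumerate(tokenize(doc.text)):
            self._postings.setdefault(token, {}).setdefault(doc.doc_id, []).append(pos)

    # -- introspection -----------------------------------------------------

    @property
    def n_documents(self) -> int:
        return len(self._doc_patient)

    @property
    def vocabulary(self) -> set[str]:
        return set(self._postings)

    @property
    def doc_ids(self) -> set[str]:
        return set(self._doc_patient)

    @property
    def patient_ids(self) -> set[str]:
        return set(self._doc_patient.values())

    def postings(self, token: str) -> dict[str, list[int]]:
        """Postings for one token (empty dict when unseen)."""
        return {d: list(p) for d, p in self._postings.get(token.lower(), {}).items()}

    # -- search ------------------------------------------------------------

    def phrase_search(self, phrase: str) -> set[str]:
        """Documents containing the phrase's tokens at consecutive positions.

        Case-insensitive; each matching document is returned once.  A phrase
        that tokenizes to nothing is an input error.
        """
        tokens = tokenize(phrase)
        if not tokens:
            raise ValueError(f"phrase {phrase!r} contains no searchable tokens")
        per_token = []
        for token in tokens:
            posting = self._postings.get(token)
            if not posting:
                return set()
            per_token.append(posting)
        candidates = set(per_token[0])
        for posting in per_token[1:]:
            candidates &= posting.keys()
        hits: set[str] = set()
        for doc_id in candidates:
            later = [set(p[doc_id]) for p in per_token[1:]]
            for start in per_token[0][doc_id]:
                if all(start + offset + 1 in positions for offset, positions in enumerate(later)):
                    hits.add(doc_id)
                    break
        return hits

    def patient_set(self, doc_ids: Iterable[str]) -> set[str]:
        """Distinct patients owning at least one of ``doc_ids``."""
        patients: set[str] = set()
        for doc_id in doc_ids:
            try:
                patients.add(self._doc_patient[doc_id])
            except KeyError:
                raise KeyError(f"unknown doc_id {doc_id!r}") from None
        return patients

    # -- snapshot ----------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write a single-file JSON snapshot with a versioned header."""
        payload = {
            "format": _SNAPSHOT_FORMAT,
            "version": _SNAPSHOT_VERSION,
            "doc_patient": dict(sorted(self._doc_patient.items())),
            "postings": {
                token: {d: self._postings[token][d] for d in sorted(self._postings[token])}
                for token in sorted(self._postings)
            },
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "InvertedIndex":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if payload.get("format") != _SNAPSHOT_FORMAT:
            raise ValueError(f"{path}: not a {_SNAPSHOT_FORMAT} snapshot")
        if payload.get("version") != _SNAPSHOT_VERSION:
            raise ValueError(f"{path}: unsupported snapshot version {payload.get('version')!r}")
        index = cls()
        index._doc_patient = dict(payload["doc_patient"])
        index._postings = {
            token: {doc: list(map(int, pos)) for doc, pos in docs.items()}
            for token, docs in payload["postings"].items()
        }
        return index


# -- module-level operation surface ---------------------------------------


def build_index(docs: Iterable[NoteDocument]) -> InvertedIndex:
    """Index every token of every document, with positions and patient map."""
    return InvertedIndex.from_documents(docs)


def phrase_search(index: InvertedIndex, phrase: str) -> set[str]:
    return index.phrase_search(phrase)


def patient_set(index: InvertedIndex, doc_ids: Iterable[str]) -> set[str]:
    return index.patient_set(doc_ids)


# -- corpus exchange format ------------------------------------------------
#
# One record per line.  TSV files carry a header line and escape tab,
# newline, and backslash inside the text field; ``.jsonl`` files carry one
# JSON object per line with the same three fields.

_TSV_HEADER = "doc_id\tpatient_id\ttext"


def _escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace("\t", "\\t").replace("\n", "\\n").replace("\r", "\\r")


def _unescape(text: str) -> str:
    out: list[str] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "\\" and i + 1 < len(text):
            nxt = text[i + 1]
            out.append({"\\": "\\", "t": "\t", "n": "\n", "r": "\r"}.get(nxt, "\\" + nxt))
            i += 2
        else:
            out.append(ch)
            i += 1
    return "".join(out)


def write_corpus(docs: Iterable[NoteDocument], path: str | Path) -> None:
    """Write notes in the exchange format; ``.jsonl`` suffix selects JSON lines."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if path.suffix == ".jsonl":
            for doc in docs:
                fh.write(
                    json.dumps(
                        {"doc_id": doc.doc_id, "patient_id": doc.patient_id, "text": doc.text}
                    )
                    + "\n"
                )
        else:
            fh.write(_TSV_HEADER + "\n")
            for doc in docs:
                fh.write(f"{doc.doc_id}\t{doc.patient_id}\t{_escape(doc.text)}\n")


def read_corpus(path: str | Path) -> list[NoteDocument]:
    """Read notes written by :func:`write_corpus`."""
    path = Path(path)
    docs: list[NoteDocument] = []
    with path.open("r", encoding="utf-8") as fh:
        if path.suffix == ".jsonl":
            for line_no, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                rec = json.loads(line)
                try:
                    docs.append(NoteDocument(rec["doc_id"], rec["patient_id"], rec["text"]))
                except KeyError as exc:
                    raise ValueError(f"{path}:{line_no}: missing field {exc}") from None
        else:
            header = fh.readline().rstrip("\n")
            if header != _TSV_HEADER:
                raise ValueError(f"{path}: expected header {_TSV_HEADER!r}, got {header!r}")
            for line_no, line in enumerate(fh, 2):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t", 2)
                if len(parts) != 3:
                    raise ValueError(f"{path}:{line_no}: expected 3 tab-separated fields")
                docs.append(NoteDocument(parts[0], parts[1], _unescape(parts[2])))
    return docs
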