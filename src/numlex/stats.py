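"""Cohort-identification impact statistics: patient overlap and missed rates.

A concept such as "stage 3 chronic kidney disease" appears in notes under
both an Arabic-numeral spelling (phrase 1) and a Roman-numeral spelling
(phrase 2).  Searching for only one spelling misses the patients whose
notes carry only the other.  With patient counts

* ``b`` — patients matched by phrase 1 only,
* ``d`` — patients matched by both phrases,
* ``e`` — patients matched by phrase 2 only,

the union cohort has ``b + d + e`` patients, and the missed percentages are

    c = 100 * e / (b + d + e)   (missed when searching only phrase 1)
    f = 100 * b / (b + d + e)   (missed when searching only phrase 2)

rounded half-away-from-zero to one decimal.  Rounding is done on exact
rationals so printed percentages are reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Iterable, Sequence

from .index import InvertedIndex

__all__ = [
    "CohortOverlap",
    "UndefinedPercentageError",
    "missed_percentages",
    "compute_overlap",
    "union_size",
    "intersection_by_inclusion_exclusion",
    "count_majority_missed",
    "frequency_table",
    "builtin_cohort_counts",
    "overlap_rows_from_counts",
    "format_overlap_table",
    "write_overlap_report",
    "write_frequency_report",
]


class UndefinedPercentageError(ValueError):
    """Raised when all three overlap counts are zero (empty union cohort)."""


def _round1_half_away(x: Fraction) -> float:
    """Round an exact rational half-away-from-zero to one decimal."""
    scaled = x * 10
    if scaled >= 0:
        n = (scaled + Fraction(1, 2)).__floor__()
    else:
        n = -((-scaled + Fraction(1, 2)).__floor__())
    return n / 10


def missed_percentages(b: int, d: int, e: int) -> tuple[float, float]:
    """Missed percentages (c, f) from the (phrase1-only, both, phrase2-only) counts.

    >>> missed_percentages(43777, 7919, 6053)
    (10.5, 75.8)
    """
    if min(b, d, e) < 0:
        raise ValueError("counts must be non-negative")
    total = b + d + e
    if total == 0:
        raise UndefinedPercentageError("all counts are zero; percentages undefined")
    c = _round1_half_away(Fraction(100 * e, total))
    f = _round1_half_away(Fraction(100 * b, total))
    return c, f


def union_size(b: int, d: int, e: int) -> int:
    """Total patients found when both phrase variants are searched."""
    if min(b, d, e) < 0:
        raise ValueError("counts must be non-negative")
    return b + d + e


def intersection_by_inclusion_exclusion(total1: int, total2: int, union: int) -> int:
    """Overlap count recovered from the two single-phrase totals and the union."""
    if not total1 + total2 >= union >= max(total1, total2):
        raise ValueError(
            f"inconsistent counts: need total1+total2 >= union >= max(total1, total2), "
            f"got ({total1}, {total2}, {union})"
        )
    return total1 + total2 - union


@dataclass(frozen=True)
class CohortOverlap:
    """One row of the cohort-overlap report (the a-g columns)."""

    phrase1: str
    phrase2: str
    n1_only: int
    n_both: int
    n2_only: int
    pct_missed_if_only_p1: float
    pct_missed_if_only_p2: float

    @classmethod
    def from_counts(cls, phrase1: str, phrase2: str, b: int, d: int, e: int) -> "CohortOverlap":
        c, f = missed_percentages(b, d, e)
        return cls(phrase1, phrase2, b, d, e, c, f)

    @property
    def total(self) -> int:
        return union_size(self.n1_only, self.n_both, self.n2_only)


def compute_overlap(index: InvertedIndex, phrase1: str, phrase2: str) -> CohortOverlap:
    """Patient-level overlap between two phrase searches over an index.

    Notes are searched per phrase, hits are aggregated to distinct patients,
    and the counts are split into phrase1-only / both / phrase2-only.
    """
    patients1 = index.patient_set(index.phrase_search(phrase1))
    patients2 = index.patient_set(index.phrase_search(phrase2))
    return CohortOverlap.from_counts(
        phrase1,
        phrase2,
        b=len(patients1 - patients2),
        d=len(patients1 & patients2),
        e=len(patients2 - patients1),
    )


def count_majority_missed(rows: Iterable[CohortOverlap], threshold: float = 50.0) -> int:
    """Rows whose larger missed percentage strictly exceeds ``threshold``."""
    if not 0 < threshold < 100:
        raise ValueError(f"threshold must be in (0, 100), got {threshold}")
    return sum(
        1 for row in rows if max(row.pct_missed_if_only_p1, row.pct_missed_if_only_p2) > threshold
    )


def frequency_table(index: InvertedIndex, terms: Sequence[str]) -> list[tuple[str, int]]:
    """Distinct-document phrase counts, one row per term, input order kept."""
    if not terms:
        raise ValueError("terms must be non-empty")
    return [(term, len(index.phrase_search(term))) for term in terms]


# ---------------------------------------------------------------------------
# built-in worked-example counts and report rendering

def builtin_cohort_counts(path: str | Path | None = None) -> list[tuple[str, int, int, int, str]]:
    """The packaged ten-row cohort count table as (phrase1, b, d, e, phrase2).

    A user file with the same TSV layout (header line, five columns) may be
    passed instead of the bundled copy.
    """
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
    else:
        text = (
            importlib_resources.files("numlex.resources")
            .joinpath("cohort_counts.tsv")
            .read_text(encoding="utf-8")
        )
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return []
    rows: list[tuple[str, int, int, int, str]] = []
    for line_no, line in enumerate(lines[1:], 2):
        parts = line.split("\t")
        if len(parts) != 5:
            raise ValueError(f"counts file line {line_no}: expected 5 fields, got {len(parts)}")
        try:
            rows.append((parts[0], int(parts[1]), int(parts[2]), int(parts[3]), parts[4]))
        except ValueError:
            raise ValueError(f"counts file line {line_no}: non-integer count") from None
    return rows


def overlap_rows_from_counts(
    counts: Iterable[tuple[str, int, int, int, str]]
) -> list[CohortOverlap]:
    return [
        CohortOverlap.from_counts(phrase1, phrase2, b, d, e)
        for phrase1, b, d, e, phrase2 in counts
    ]


def format_overlap_table(rows: Sequence[CohortOverlap], threshold: float | None = 50.0) -> str:
    """Render the seven-column overlap report as aligned text."""
    header = (
        "phrase1", "n1_only", "pct_missed_p1_only", "n_both",
        "n2_only", "pct_missed_p2_only", "phrase2", "total", "flag",
    )
    lines = ["\t".join(header)]
    for row in rows:
        flag = ""
        if threshold is not None and max(
            row.pct_missed_if_only_p1, row.pct_missed_if_only_p2
        ) > threshold:
            flag = f">{threshold:g}%"
        lines.append(
            f"{row.phrase1}\t{row.n1_only}\t{row.pct_missed_if_only_p1:.1f}\t{row.n_both}\t"
            f"{row.n2_only}\t{row.pct_missed_if_only_p2:.1f}\t{row.phrase2}\t{row.total}\t{flag}"
        )
    return "\n".join(lines)


def write_overlap_report(
    rows: Sequence[CohortOverlap], path: str | Path, threshold: float | None = 50.0
) -> None:
    """Write the overlap report; ``.json`` suffix selects the structured twin."""
    path = Path(path)
    if path.suffix == ".json":
        payload = [
            {
                "phrase1": r.phrase1,
                "n1_only": r.n1_only,
                "pct_missed_if_only_p1": r.pct_missed_if_only_p1,
                "n_both": r.n_both,
                "n2_only": r.n2_only,
                "pct_missed_if_only_p2": r.pct_missed_if_only_p2,
                "phrase2": r.phrase2,
                "total": r.total,
            }
            for r in rows
        ]
        path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    else:
        path.write_text(format_overlap_table(rows, threshold) + "\n", encoding="utf-8")


def write_frequency_report(rows: Sequence[tuple[str, int]], path: str | Path) -> None:
    """Two-column delimited frequency report (term, distinct-document count)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("term\tn_documents\n")
        for term, count in rows:
            fh.write(f"{term}\t{count}\n")
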