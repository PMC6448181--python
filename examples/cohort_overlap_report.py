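"""Cohort-overlap report from patient-count triples.

Renders the packaged ten-row worked example: for each concept, the number
of patients found only by the Arabic-numeral phrase (b), by both (d), and
only by the Roman-numeral phrase (e), with the percentage of the combined
cohort missed when only one spelling is searched.  Rows where a
single-spelling search misses a majority of patients are flagged.
"""

from numlex import (
    builtin_cohort_counts,
    count_majority_missed,
    intersection_by_inclusion_exclusion,
    overlap_rows_from_counts,
    union_size,
)
from numlex.stats import format_overlap_table

rows = overlap_rows_from_counts(builtin_cohort_counts())
print(format_overlap_table(rows, threshold=50.0))
print()
print(f"{count_majority_missed(rows, 50.0)} of {len(rows)} concepts lose a majority "
      "of their cohort to a single-spelling search.")

# the astrocytoma row, reconstructed from single-phrase totals
row = next(r for r in rows if "astrocytoma" in r.phrase1)
total1 = row.n1_only + row.n_both   # patients found by the Arabic phrase
total2 = row.n_both + row.n2_only   # patients found by the Roman phrase
union = union_size(row.n1_only, row.n_both, row.n2_only)
overlap = intersection_by_inclusion_exclusion(total1, total2, union)
print(f"astrocytoma: single-phrase totals {total1} and {total2} look interchangeable, "
      f"but only {overlap} patients overlap; the union cohort has {union}.")
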