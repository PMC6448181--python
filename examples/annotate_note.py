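"""Annotate and normalize the numeric spans of one clinical-style note.

Shows span detection (category, canonical value, validity, ambiguity) and
the conservative normalization pass: unambiguous integer spans become
Arabic digits, while ambiguous tokens ("iv" could be intravenous) and
invalid values ("june 31", "135 year old") are left untouched.
"""

from numlex import annotate_document, normalize_document, tokenize

note = (
    "Patient is a 135 year old with type II diabetes, given IV fluids. "
    "Scheduled follow-up on June 31; tanner stage iiii documented, 1rd visit."
)
tokens = tokenize(note)
print("tokens:", tokens)
print()
for span in annotate_document(tokens):
    flags = []
    if span.ambiguous:
        flags.append("ambiguous")
    if span.validity.value != "well_formed":
        flags.append(span.validity.value)
    print(f"  [{span.start_token:2d},{span.end_token:2d}) {span.surface!r:20} "
          f"{span.category.value:25} value={span.canonical_value} {' '.join(flags)}")
print()
print("normalized:", " ".join(normalize_document(tokens)))
print("('ii' became 2 and 'iiii' became 4; 'iv', the invalid date, and the")
print(" implausible age were deliberately left as written.)")
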