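import pytest

from numlex import NoteDocument, build_index


@pytest.fixture
def small_corpus():
    """Six notes over three patients with Arabic/Roman variant phrases."""
    return [
        NoteDocument("d1", "pA", "Patient with type 2 diabetes mellitus, stable."),
        NoteDocument("d2", "pA", "Follow-up for type II diabetes mellitus today."),
        NoteDocument("d3", "pB", "History of type 2 diabetes mellitus."),
        NoteDocument("d4", "pB", "Mallampati score: IV noted before induction."),
        NoteDocument("d5", "pC", "Seen for type II diabetes mellitus management."),
        NoteDocument("d6", "pC", "No numeric phrases in this note at all."),
    ]


@pytest.fixture
def small_index(small_corpus):
    return build_index(small_corpus)
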