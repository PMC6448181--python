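"""Surface-form generators: cardinals, ordinals, dates, ages, classifications."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from numlex.variants import (
    SurfaceForm,
    UnsupportedPhraseError,
    Validity,
    VariantCategory,
    age_phrases,
    classification_variants,
    date_strings,
    decade_age_term,
    dimension_phrase,
    expand_phrase,
    fraction_phrase,
    generate_malformed_romans,
    generate_ordinal_variants,
    int_to_cardinal_words,
    cardinal_words_to_int,
    negative_forms,
    ordinal_suffix,
    range_phrase,
    tuple_terms,
)


def _oracle_suffix(n: int) -> str:
    """Independent last-two-digit coding of the ordinal-suffix rule."""
    s = str(n)
    if len(s) >= 2 and s[-2] == "1":
        return "th"
    return {"1": "st", "2": "nd", "3": "rd"}.get(s[-1], "th")


class TestCardinalWords:
    @pytest.mark.parametrize(
        "n, words",
        [(0, "zero"), (3, "three"), (13, "thirteen"), (33, "thirty-three"),
         (73, "seventy-three"), (40, "forty"), (100, "one hundred"),
         (101, "one hundred one"), (999, "nine hundred ninety-nine")],
    )
    def test_spellings(self, n, words):
        assert int_to_cardinal_words(n) == words

    @pytest.mark.parametrize("n", [-1, 1000])
    def test_domain(self, n):
        with pytest.raises(ValueError):
            int_to_cardinal_words(n)

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(min_value=0, max_value=999))
    def test_roundtrip(self, n):
        assert cardinal_words_to_int(int_to_cardinal_words(n)) == n

    def test_hyphen_and_space_forms_equivalent(self):
        assert cardinal_words_to_int("thirty three") == 33
        assert cardinal_words_to_int("thirty-three") == 33


class TestOrdinals:
    def test_suffix_against_oracle(self):
        assert all(ordinal_suffix(n) == _oracle_suffix(n) for n in range(1, 10001))

    @pytest.mark.parametrize("n, suffix", [(1, "st"), (3, "rd"), (11, "th"), (21, "st"),
                                           (111, "th"), (112, "th"), (13, "th")])
    def test_suffix_examples(self, n, suffix):
        assert ordinal_suffix(n) == suffix

    def test_variants_for_one(self):
        forms = {f.text: f for f in generate_ordinal_variants(1)}
        assert forms["1st"].validity is Validity.WELL_FORMED
        for wrong in ("1rd", "1nd", "1th"):
            assert forms[wrong].validity is Validity.MALFORMED
            assert forms[wrong].canonical_value == 1
        assert forms["first"].validity is Validity.WELL_FORMED
        assert forms["firstly"].validity is Validity.WELL_FORMED
        assert forms["1stly"].validity is Validity.MALFORMED
        assert forms["primary"].validity is Validity.WELL_FORMED
        assert forms["1ary"].validity is Validity.MALFORMED

    def test_hybrid_ary_and_ly_forms(self):
        texts2 = {f.text for f in generate_ordinal_variants(2)}
        assert {"2ndary", "2ary", "secondary", "secondly", "2ndly"} <= texts2
        texts3 = {f.text for f in generate_ordinal_variants(3)}
        assert "3rdly" in texts3 and "tertiary" in texts3

    def test_malformed_forms_have_wellformed_counterpart(self):
        """Every malformed form shares its canonical value with a well-formed one."""
        for n in range(1, 10):
            forms = generate_ordinal_variants(n)
            well = {f.canonical_value for f in forms if f.validity is Validity.WELL_FORMED}
            for f in forms:
                if f.validity is Validity.MALFORMED:
                    assert f.canonical_value in well


class TestMalformedRomans:
    @pytest.mark.parametrize("n", range(4, 10))
    def test_i_runs(self, n):
        forms = generate_malformed_romans(n)
        texts = {f.text for f in forms}
        assert "i" * n in texts
        for f in forms:
            assert f.validity is Validity.MALFORMED
            assert f.canonical_value == n

    def test_strict_form_never_emitted(self):
        from numlex.roman import int_to_roman

        for n in range(4, 10):
            texts = {f.text for f in generate_malformed_romans(n, include_additive_v_forms=True)}
            assert int_to_roman(n).lower() not in texts

    def test_domain(self):
        with pytest.raises(ValueError):
            generate_malformed_romans(3)
        with pytest.raises(ValueError):
            generate_malformed_romans(10, max_run=9)


class TestPhrases:
    @pytest.mark.parametrize(
        "num, den, text", [(1, 3, "one third"), (2, 3, "two thirds"),
                           (1, 2, "one half"), (2, 2, "two halves"), (6, 8, "six eighths")]
    )
    def test_fraction_agreement(self, num, den, text):
        forms = fraction_phrase(num, den)
        assert forms[0].text == text
        assert forms[0].canonical_value == (num, den)

    def test_fraction_errors(self):
        forms = fraction_phrase(1, 3, include_errors=True)
        by_text = {f.text: f for f in forms}
        assert by_text["one thirds"].validity is Validity.MALFORMED

    @pytest.mark.parametrize("a, b, text", [(2, 4, "two by four"), (1, 3, "one by three"),
                                            (1, 1, "one by one")])
    def test_dimension(self, a, b, text):
        assert dimension_phrase(a, b) == text

    @pytest.mark.parametrize("a, b, text", [(1, 3, "one to three"), (2, 4, "two to four"),
                                            (5, 5, "five to five")])
    def test_range(self, a, b, text):
        assert range_phrase(a, b) == text

    @pytest.mark.parametrize("n, expected", [
        (5, {"minus five", "minus 5", "negative five", "negative 5"}),
        (1, {"minus one", "minus 1", "negative one", "negative 1"}),
        (10, {"minus ten", "minus 10", "negative ten", "negative 10"}),
    ])
    def test_negative_forms(self, n, expected):
        forms = negative_forms(n)
        assert {f.text for f in forms} == expected
        assert all(f.canonical_value == -n for f in forms)


class TestDatesAndAges:
    def test_invalid_dates(self):
        (jan35,) = date_strings(1, 35)
        assert jan35.text == "january 35"
        assert jan35.validity is Validity.INVALID_VALUE
        june31 = date_strings(6, 31, with_suffix=True)
        assert june31[1].text == "june 31st"
        assert all(f.validity is Validity.INVALID_VALUE for f in june31)

    def test_valid_31sts(self):
        for month in (1, 3, 5, 7, 8, 10, 12):
            (form,) = date_strings(month, 31)
            assert form.validity is Validity.WELL_FORMED

    @pytest.mark.parametrize(
        "age, validity",
        [(135, Validity.INVALID_VALUE), (123, Validity.INVALID_VALUE),
         (122, Validity.WELL_FORMED), (0, Validity.WELL_FORMED)],
    )
    def test_age_plausibility_boundary(self, age, validity):
        forms = age_phrases(age)
        assert forms[0].text == f"{age} year old"
        assert all(f.validity is validity for f in forms)

    @pytest.mark.parametrize(
        "age, word",
        [(50, "quinquagenarian"), (65, "sexagenarian"), (75, "septuagenarian"),
         (85, "octogenarian"), (95, "nonagenarian"), (105, "centenarian"),
         (110, "supercentenarian"), (130, "supercentenarian"), (45, None), (0, None)],
    )
    def test_decade_terms(self, age, word):
        assert decade_age_term(age) == word


class TestTuplesAndClassifications:
    def test_tuple_three(self):
        texts = {f.text for f in tuple_terms(3)}
        assert {"triple", "tripling", "tripled", "triples", "triplets"} <= texts

    def test_tuple_irregular_offspring(self):
        assert "singleton" in {f.text for f in tuple_terms(1)}
        texts2 = {f.text for f in tuple_terms(2)}
        assert "twins" in texts2 and "doublets" not in texts2

    def test_type_two(self):
        texts = {f.text for f in classification_variants("type", 2)}
        assert texts == {"type 2", "type ii"}

    def test_stage_3b(self):
        texts = {f.text for f in classification_variants("stage", 3, "b")}
        assert {"3b", "iiib", "stage 3b", "stage iiib", "stage 3", "stage iii"} <= texts

    def test_score_four(self):
        texts = {f.text for f in classification_variants("score", 4)}
        assert texts == {"score 4", "score iv"}

    def test_roman_letter_i_compound_suppressed(self):
        """iii+i would spell the malformed numeral iiii, so it is not emitted."""
        texts = {f.text for f in classification_variants("stage", 3, "i")}
        assert "iiii" not in texts
        assert "3i" in texts


class TestExpandPhrase:
    @pytest.mark.parametrize(
        "phrase, expected_member",
        [("stage 3 chronic kidney disease", "stage iii chronic kidney disease"),
         ("type 2 diabetes mellitus", "type ii diabetes mellitus"),
         ("grade iii anaplastic astrocytoma", "grade 3 anaplastic astrocytoma"),
         ("factor 9 deficiency", "factor ix deficiency")],
    )
    def test_substitution(self, phrase, expected_member):
        assert expected_member in expand_phrase(phrase)

    def test_reflexive_and_deterministic(self):
        phrase = "mallampati score: iv"
        first = expand_phrase(phrase)
        assert phrase in first
        assert first == expand_phrase(phrase)

    def test_identity_without_numeric_token(self):
        assert expand_phrase("no numbers here") == {"no numbers here"}

    def test_multiple_numeric_tokens_rejected(self):
        with pytest.raises(UnsupportedPhraseError):
            expand_phrase("2 by 4")

    def test_all_three_spellings_present(self):
        expanded = expand_phrase("tanner stage 3")
        assert {"tanner stage 3", "tanner stage iii", "tanner stage three"} <= expanded


def test_surface_forms_are_lowercase_nonempty():
    with pytest.raises(ValueError):
        SurfaceForm("", VariantCategory.DATE)
    with pytest.raises(ValueError):
        SurfaceForm("June 31", VariantCategory.DATE)
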