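"""Synthetic corpus generation: determinism, ledger identity, rate recovery."""

import math

import pytest

from numlex.index import build_index, tokenize
from numlex.stats import compute_overlap
from numlex.synth import (
    ConfigError,
    GroundTruthLedger,
    InjectionSpec,
    demo_specs,
    generate_corpus,
    ledger_counts,
    load_corpus_config,
    verify_ledger,
)

N_PATIENTS = 400
SEED = 20260926


def _spec(**overrides):
    base = dict(
        template="stage <N> chronic kidney disease",
        value=3,
        variant_probs={"arabic": 0.6, "roman": 0.35, "word": 0.05},
        prevalence=0.5,
    )
    base.update(overrides)
    return InjectionSpec(**base)


class TestConfigValidation:
    def test_probs_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            _spec(variant_probs={"arabic": 0.5, "roman": 0.2, "word": 0.1})

    def test_unknown_variant_rejected(self):
        with pytest.raises(ConfigError):
            _spec(variant_probs={"arabic": 0.5, "klingon": 0.5})

    def test_template_needs_slot(self):
        with pytest.raises(ConfigError):
            _spec(template="no slot here")

    def test_unknown_error_kind_rejected(self):
        with pytest.raises(ConfigError):
            _spec(error_rates={"typo": 0.1})

    def test_phrases(self):
        spec = _spec()
        assert spec.phrase("arabic") == "stage 3 chronic kidney disease"
        assert spec.phrase("roman") == "stage iii chronic kidney disease"
        assert spec.phrase("word") == "stage three chronic kidney disease"


class TestDeterminism:
    def test_same_seed_identical_corpora(self):
        docs1, _ = generate_corpus([_spec()], 50, seed=SEED)
        docs2, _ = generate_corpus([_spec()], 50, seed=SEED)
        assert docs1 == docs2

    def test_different_seed_differs(self):
        docs1, _ = generate_corpus([_spec()], 50, seed=SEED)
        docs2, _ = generate_corpus([_spec()], 50, seed=SEED + 1)
        assert docs1 != docs2


class TestDegenerateMixtures:
    def test_all_arabic(self):
        spec = _spec(prevalence=1.0, variant_probs={"arabic": 1.0, "roman": 0.0, "word": 0.0})
        docs, ledger = generate_corpus([spec], 60, seed=SEED)
        b, d, e = ledger_counts(ledger, spec.concept)
        assert (b, d, e) == (60, 0, 0)
        index = build_index(docs)
        patients = index.patient_set(index.phrase_search(spec.phrase("arabic")))
        assert len(patients) == 60
        assert index.phrase_search(spec.phrase("roman")) == set()

    def test_partition_sums_to_affected_patients(self):
        spec = _spec(variant_probs={"arabic": 0.5, "roman": 0.5, "word": 0.0})
        _, ledger = generate_corpus([spec], N_PATIENTS, seed=SEED)
        b, d, e = ledger_counts(ledger, spec.concept)
        assert b + d + e == len(ledger.patients(spec.concept))


class TestEndToEndIdentity:
    def test_overlap_matches_ledger_for_every_concept(self):
        specs = demo_specs()
        docs, ledger = generate_corpus(specs, N_PATIENTS, seed=SEED)
        index = build_index(docs)
        for spec in specs:
            row = compute_overlap(index, spec.phrase("arabic"), spec.phrase("roman"))
            assert (row.n1_only, row.n_both, row.n2_only) == ledger_counts(ledger, spec.concept)

    def test_filler_hygiene(self):
        """No configured phrase occurs outside its ledgered injections."""
        specs = demo_specs()
        docs, ledger = generate_corpus(specs, 100, seed=SEED, verify=False)
        verify_ledger(docs, ledger, specs)  # raises on any stray occurrence

    def test_verify_catches_tampering(self):
        specs = [_spec(prevalence=1.0)]
        docs, ledger = generate_corpus(specs, 10, seed=SEED)
        tampered = [d for d in docs]
        from numlex.index import NoteDocument

        tampered[0] = NoteDocument(
            tampered[0].doc_id, tampered[0].patient_id,
            tampered[0].text + " stage 3 chronic kidney disease",
        )
        with pytest.raises(RuntimeError, match="ledger mismatch"):
            verify_ledger(tampered, ledger, specs)


class TestErrorInjection:
    def test_error_forms_ledgered_and_present(self):
        spec = _spec(error_rates={"invalid_date": 0.2, "malformed_roman": 0.2})
        docs, ledger = generate_corpus([spec], 100, seed=SEED)
        by_doc = {doc.doc_id: doc for doc in docs}
        assert ledger.errors.get("invalid_date")
        for kind, pairs in ledger.errors.items():
            for doc_id, surface in pairs:
                tokens = tokenize(by_doc[doc_id].text)
                probe = tokenize(surface)
                assert any(
                    tokens[i : i + len(probe)] == probe for i in range(len(tokens))
                ), (kind, doc_id, surface)


class TestRateRecovery:
    def test_realized_roman_fraction_near_configured(self):
        """Mean realized Roman-usage fraction over seeds sits near 0.35."""
        spec = _spec()
        p_roman = spec.variant_probs["roman"]
        fractions = []
        for s in range(10):
            _, ledger = generate_corpus([spec], N_PATIENTS, seed=SEED + s, verify=False)
            counts = ledger.variant_mention_counts(spec.concept)
            fractions.append(counts["roman"] / sum(counts.values()))
        mean = sum(fractions) / len(fractions)
        sd = math.sqrt(sum((f - mean) ** 2 for f in fractions) / (len(fractions) - 1))
        assert abs(mean - p_roman) <= 3 * sd / math.sqrt(len(fractions))

    def test_overlap_fractions_match_mixture_model(self):
        """Realized both/only fractions track the closed-form note-mixture model."""
        spec = _spec(prevalence=1.0)
        notes_mean, notes_max = 3.0, 20
        _, ledger = generate_corpus(
            [spec], 2000, seed=SEED, notes_mean=notes_mean, notes_max=notes_max, verify=False
        )
        b, d, e = ledger_counts(ledger, spec.concept)
        n = len(ledger.patients(spec.concept))

        # independent oracle: truncated-geometric note count, iid variant draws
        q = 1.0 - 1.0 / notes_mean
        pmf = [(1 - q) * q ** (k - 1) for k in range(1, notes_max)]
        pmf.append(q ** (notes_max - 1))  # lumped tail
        pa = spec.variant_probs["arabic"]
        pr = spec.variant_probs["roman"]
        pw = spec.variant_probs["word"]
        exp_only_a = exp_only_r = exp_both = 0.0
        for k, pk in enumerate(pmf, start=1):
            no_a, no_r, neither = (1 - pa) ** k, (1 - pr) ** k, pw ** k
            exp_only_a += pk * (no_r - neither)
            exp_only_r += pk * (no_a - neither)
            exp_both += pk * (1 - no_a - no_r + neither)

        for observed, expected in ((b, exp_only_a), (e, exp_only_r), (d, exp_both)):
            se = math.sqrt(expected * (1 - expected) / n)
            assert abs(observed / n - expected) <= 4 * se + 0.01, (observed / n, expected)


class TestConfigFile:
    def test_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "config.yaml"
        path.write_text(
            "n_patients: 25\n"
            "seed: 11\n"
            "specs:\n"
            "  - template: 'phase <N> clinical trial'\n"
            "    value: 1\n"
            "    variant_probs: {arabic: 0.7, roman: 0.3}\n"
            "    prevalence: 0.4\n"
        )
        config = load_corpus_config(path)
        assert config["n_patients"] == 25
        assert config["specs"][0].phrase("roman") == "phase i clinical trial"
        docs, ledger = generate_corpus(config["specs"], config["n_patients"], config["seed"])
        assert docs and ledger.concepts == ["phase <N> clinical trial"]

    def test_bad_yaml_is_config_error(self, tmp_path):
        path = tmp_path / "config.yaml"
        path.write_text("specs: [\n")
        with pytest.raises(ConfigError):
            load_corpus_config(path)

    def test_missing_fields_is_config_error(self, tmp_path):
        path = tmp_path / "config.yaml"
        path.write_text("n_patients: 5\nseed: 1\n")
        with pytest.raises(ConfigError):
            load_corpus_config(path)


def test_ledger_json_roundtrip(tmp_path):
    specs = demo_specs()
    _, ledger = generate_corpus(specs, 50, seed=SEED)
    path = tmp_path / "ledger.json"
    ledger.to_json(path)
    loaded = GroundTruthLedger.from_json(path)
    for spec in specs:
        assert ledger_counts(loaded, spec.concept) == ledger_counts(ledger, spec.concept)
    assert loaded.errors == ledger.errors


def test_unknown_concept_rejected():
    _, ledger = generate_corpus([_spec()], 10, seed=SEED)
    with pytest.raises(KeyError):
        ledger_counts(ledger, "nonexistent <N> concept")
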