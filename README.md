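# numlex — numeric lexical variants in clinical text

Free-text clinical notes write the same number many ways: `type 2` vs
`type II` vs `T2DM`, `3rd` vs `third` vs the erroneous `1rd`, strict Roman
numerals (`IV`) next to malformed additive ones (`IIII`), impossible dates
(`June 31`), and biologically implausible ages (`135 year old`).  A search
or information-extraction pipeline that knows only one spelling silently
loses patients.  `numlex` is a library (plus a thin CLI) for people who
build or audit such pipelines — clinical NLP engineers and research
informaticians doing EHR cohort identification — and it provides:

* **Generators** for twelve numeric variant categories (integers spelled as
  words, negatives, fractions, dimensions, ranges, dates, Roman numerals,
  medical classifications, ages, quantity expressions, ordering/ranking,
  tuples), including the deliberately malformed and invalid forms that occur
  in real notes.
* **Detectors** that map any surface string back to a category, canonical
  value, and validity flag, plus span annotation and a conservative
  normalizer.  Every generator output round-trips through the detector
  (generator/detector duality).
* A **positional inverted index** with case-insensitive exact phrase search
  and distinct-document / distinct-patient counting.  Stop words are kept:
  in clinical text they double as acronyms (OR, IS, AND).
* **Cohort-overlap statistics.**  For a concept with an Arabic-numeral
  phrase and a Roman-numeral phrase, let `b`, `d`, `e` be the patients found
  by only the first, by both, and by only the second.  The union cohort has
  `n = b + d + e` patients and the *missed percentages* are

  ```
  c = 100 · e / n   (missed searching only the Arabic phrase)
  f = 100 · b / n   (missed searching only the Roman phrase)
  ```

  rounded half-away-from-zero to one decimal on exact rationals.
* A **synthetic corpus generator** that injects variant phrases into
  clinical-flavoured filler text at configured per-variant probabilities,
  with a ground-truth ledger recording every injection — the oracle for
  end-to-end recovery tests.

## Worked example

```python
>>> from numlex import missed_percentages, expand_phrase, classify_surface
>>> missed_percentages(43777, 7919, 6053)   # diabetes row: b, d, e
(10.5, 75.8)
>>> sorted(expand_phrase("stage 3 chronic kidney disease"))
['stage 3 chronic kidney disease', 'stage iii chronic kidney disease', 'stage three chronic kidney disease']
>>> classify_surface("june 31st").validity
<Validity.INVALID_VALUE: 'invalid_value'>
```

The first call says: searching only `type 2 diabetes mellitus` misses 10.5%
of the combined cohort, while searching only the Roman spelling misses
75.8%.  Longer narratives live in `examples/` — each script builds a small
input, runs one capability, and prints what the numbers mean:

```bash
python examples/cohort_overlap_report.py   # ten-concept overlap table; 8/10 rows lose >50%
python examples/expand_and_search.py       # query expansion recovers all spellings
python examples/synthetic_end_to_end.py    # searched counts == ledger, exactly
python examples/annotate_note.py           # span annotation and safe normalization
```

The command-line interface mirrors the pipeline
(`numlex generate | index | search | overlap | frequencies | annotate |
demo-table18 | run`); `numlex run -c config.yaml -o out/` does
generate → index → overlap → report in one deterministic invocation.

## Layout

```
src/numlex/
  variants.py   generators for the twelve variant categories
  detect.py     classification, annotation, normalization
  roman.py      strict/lenient Roman numeral conversion and parsing
  validity.py   calendar and age-plausibility rules
  lexicons.py   plain-text lexicon resources (scale words, decade terms, ...)
  index.py      tokenizer, positional inverted index, corpus I/O
  stats.py      overlap counts, missed percentages, reports
  synth.py      seeded synthetic corpus generator with ground-truth ledger
  cli.py        thin click CLI over the above
docs/methods.md   model, parameters, numerical choices, limitations
```
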