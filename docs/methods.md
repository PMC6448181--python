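# Methods

## The problem being modelled

Clinical notes express numbers through many surface spellings — Arabic
digits, Roman numerals, spelled-out words, ordinal suffixes, and hybrid or
erroneous forms — and search over such notes is typically exact-phrase
matching over an inverted index.  The package models the consequence:
cohort identification by phrase search is only as complete as the set of
spellings searched.  The core statistic is the *missed percentage*.  For a
concept with an Arabic-numeral phrase and a Roman-numeral phrase, the
patient universe of interest is the union cohort, partitioned into counts
`b` (Arabic-only), `d` (both), and `e` (Roman-only); searching only the
Arabic phrase misses `c = 100·e/(b+d+e)` percent of it, and only the Roman
phrase misses `f = 100·b/(b+d+e)`.

These are descriptive statistics of a fixed corpus, not estimates with
sampling error, so no confidence intervals are attached.

## Surface-form model

Every generated or detected string is a `SurfaceForm` with a category (one
of twelve), an optional canonical value (an integer, a numerator/denominator
pair, or a month/day pair), and a three-way validity flag:

* *well_formed* — correct ordinary spelling;
* *malformed* — a spelling error with a well-formed counterpart of the same
  value (`iiii`→4, `1rd`→1st, `2ndary`→secondary).  Malformed forms are
  recoverable: a lenient reader can still extract the value;
* *invalid_value* — correctly spelled but violating a domain rule
  (`june 31`, `135 year old`).  Invalid values are *not* recoverable; they
  flag a data-quality problem, and the normalizer refuses to touch them.

The generators and the classifier are exact inverses over the generators'
full domains (checked exhaustively, ~10,800 forms); this duality is the
package's internal consistency guarantee.

## Rules and their parameters

**Roman numerals.**  Strict form = unique subtractive spelling, domain
1–3999 (the boundary of plain subtractive notation; no overline forms).
The lenient parser values any symbol string by summing symbol values with
subtractive pairs honoured, flagging non-canonical input as malformed.
Malformed *generation* is restricted to the pure repeated-I runs of length
4–9 observed in practice; additive V+I forms are available behind a flag.

**Ordinal suffixes.**  Determined by the last two digits: a tens digit of 1
forces `th`; otherwise the last digit selects st/nd/rd/th.  Verified against
an independently coded oracle on 1–10,000.

**Calendar validity.**  Dates in notes carry no year, so validity is decided
from (month, day) alone with month lengths 31/28(29)/31/30/31/30/31/31/30/
31/30/31.  February 29 is governed by a policy: the default `lenient_feb29`
accepts it (some year makes it valid); `strict_feb29` rejects it.  Both
policies are checked against a `datetime`-based oracle over all month ×
day 1–39 pairs.

**Age plausibility.**  A single configurable bound, default 122 years (the
longest documented human lifespan): 122 is plausible, 123 is not.  Decade
terms (quinquagenarian … supercentenarian) are a lexicon starting at 50;
below 50 no term is returned rather than inventing one, and at 110+ the most
specific bracket (supercentenarian) wins over centenarian.

**Classification compounds.**  `type/phase/grade/stage/class/score` ×
1–5 × optional letter a–j, in Arabic and Roman spellings, with and without
the prefix word.  Two deliberate refinements: (1) a Roman-letter token that
is a strict numeral or a pure-additive string is always read as a numeral,
never as a roman+letter compound — otherwise `ii` would parse as i+I and
`iiii` as iii+I; symmetrically the generator skips roman+letter compounds
whose concatenation spells a numeral (only letter *i* triggers this).
(2) Detection of bare compounds (`3b`, `iiib`, `va`, `if`) is permissive by
design; genuinely ambiguous ones are handled by the ambiguity flag below.

**Query expansion.**  A phrase with exactly one numeric token (digits,
strict Roman, or cardinal word, value 1–39) expands to the three spellings.
Phrases with several numeric tokens (`2 by 4`) are rejected as unsupported
rather than guessed at, since the intended joint expansion is not well
defined.

## Tokenization and search

Tokens are maximal runs of ASCII letters and digits over lowercased text;
every other character separates and is discarded.  This single rule yields
the distinctions the analysis needs: `T2DM` is one token, `DM 2` is two,
`thirty-three` splits at the hyphen, `score: IV` drops the colon.  How the
original production systems tokenize edge cases such as `2/2` or decimals
is not claimed to be matched; this package's behaviour follows the stated
separator contract.  Stop words are indexed.  Phrase search requires exact
consecutive positions (no slop) and counts a document once; patient counts
aggregate document hits through the doc→patient map (note-level search,
then patient aggregation).  The index is in-memory with a versioned
single-file JSON snapshot; the intended scale is up to ~10⁶ synthetic notes
on one machine.

## Ambiguity

Single-letter Roman tokens (`i`, `v`, `x`, and any other single Roman
symbol) and a lexicon of known collisions (`iv` intravenous, `va`, `ic`,
`id`, `if`, `1g`, `3d`) are annotated `ambiguous=True` and never
normalized.  No contextual word-sense disambiguation is attempted — the
flag marks exactly where such a component would plug in.  Span annotation
is longest-match, left-to-right, non-overlapping; classification prefix
words are treated as context, so in `type ii diabetes` the span covers
`ii`.  That choice (rather than spanning `type ii`) keeps annotation aligned
with its purpose, numeral normalization.

## Rounding

Missed percentages are rounded half-away-from-zero to one decimal, computed
on exact `Fraction`s so results are platform-independent.  This rule
reproduces all twenty percentages of the packaged ten-concept worked
example from their integer count triples; before rounding,
`c + f + 100·d/n = 100` exactly.

## Synthetic corpus generator

The generator emulates the structure the overlap analysis assumes, with all
randomness from one `random.Random(seed)` stream (fixed seed ⇒ byte-identical
corpora):

* **Notes per patient**: truncated geometric, default mean 3, maximum 20
  (tail mass lumped at the maximum).  Real per-patient note distributions
  are unknown here; this is a free modelling choice, not an estimate.
* **Concept injection**: each patient carries a concept with probability
  `prevalence`; each note of a carrier mentions it with probability
  `mention_prob` (default 1), drawing the Arabic/Roman/word spelling iid
  from `variant_probs`.  "Both-spelling" patients therefore arise naturally
  from having several notes, and the expected overlap fractions have a
  closed form used as an independent oracle in the tests.
* **Error forms** (`iiii`, `1rd`, `june 31`, `135 year old`, …) are injected
  as standalone sentences at per-note rates, so their locations are
  independently ledgered.
* **Filler hygiene by construction**: the filler vocabulary excludes every
  token of every configured phrase and error surface, so no phrase can occur
  where the ledger does not record it.  A post-generation scan re-verifies
  this by direct token matching (on by default).

The packaged demonstration conditions (`demo_specs()`) use three concepts
with variant mixtures 0.60/0.35/0.05, 0.75/0.20/0.05, and 0.40/0.55/0.05
and prevalences 0.15/0.25/0.05 — synthetic round numbers chosen once to
span Arabic-dominant and Roman-dominant regimes, not estimates of any real
corpus.

**What passing synthetic tests shows and does not show.**  Exact agreement
between searched overlap counts and the ledger demonstrates that the
tokenizer, index, phrase search, and patient aggregation are lossless on
text whose ground truth is known.  It says nothing about recall on real
notes, whose spelling variety, copy-paste duplication, and contextual
ambiguity the generator deliberately does not model.

## Problem sizes and numerical choices

The test suite and the acceptance script run the duality sweep over the
complete generator domains (~10,800 forms), the Roman round trip over all
of 1–3999, the calendar oracle over all 936 (policy, month, day) cells, the
ordinal oracle over 1–10,000, and the end-to-end synthetic experiment at
2,000 patients, with variant-usage rate recovery averaged over 50 seeds —
sizes at which every check is exact or has negligible Monte-Carlo error
while the whole suite stays fast.  Probability parameters are validated to
sum to 1 within 1e-9; percentage arithmetic uses exact rationals, so no
other tolerances are needed.  Empty cohorts raise an error rather than
reporting 0% — a silent zero would mask a broken search.

## Known limitations

* No word-sense disambiguation; ambiguity is flagged only.
* No spelling-error variants ("sevin"), unit variants ("lbs", "#"), or
  non-English numerals.
* Fraction/date collisions like `2/2` are not resolved (the tokenizer
  splits it to two bare digits).
* Cardinal words are generated up to 999; larger magnitudes are lexicon
  words (hundred … undecillion, googol), not full number-to-words
  conversion.
* The synthetic generator does not model realistic clinical language,
  copy-paste duplication, or de-identification artefacts.
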