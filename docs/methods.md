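# Methods

This note records the scoring model, the conventions chosen where the
published metric definitions leave room, the synthetic-data model, and the
limits of what the test suite shows.

## Normalization

All metrics compare *normalized* strings: full Unicode case folding, removal
of every character in Unicode general categories P* (punctuation) and
S* (symbols), collapse of any whitespace run to a single space, and
stripping of leading/trailing whitespace. Tokens are maximal non-whitespace
runs of the normalized text; joining them with single spaces reproduces the
text exactly, and normalization is idempotent.

Two sub-rules matter in practice and are configurable
(`NormalizationRules`):

* **Dash/connector punctuation separates words.** Hyphens, underscores and
  slashes become a space (`blue-green` → `blue green`); deleting them would
  silently merge words into tokens no listener typed. All other punctuation
  is deleted in place (`it's` → `its`), mirroring common transcription
  practice.
* **Category-based, not list-based.** Using Unicode categories rather than
  an ASCII punctuation list keeps normalization language-independent, so the
  metrics apply to any orthography a UTF-8 string can carry. Digits and
  other non-letter word characters are kept as token content.

Whether intra-word punctuation should separate or merge is genuinely
underdetermined by scoring practice; both behaviours are exposed and the
defaults above are the package's choice.

## Metric conventions

**Levenshtein** operates on the full normalized string including spaces, so
sentence-level distances count edits on the separators too (the 27-edit
sentence example requires this).

**Jaro** follows the classic census-linkage formulation. Matching is greedy:
scanning the response left to right, each character matches the leftmost
not-yet-matched identical character of the target within the positional
window `max(0, ⌊max(A,B)/2⌋ − 1)`. Tests verify against a brute-force search
over all legal within-window matchings that this greedy pass attains the
maximal match count. Transpositions are half the number of positions at
which the two matched character sequences disagree, rounded down — the
standard convention; the worked examples all have n = 0 and cannot
disambiguate it, so the brute-force-checked convention is adopted. Edge
cases: two empty strings are identical (distance 0); exactly one empty
string matches nothing (distance 1); s = 0 gives distance 1. Note the window
formula makes two-character swaps unmatchable (`ab` vs `ba` → window 0 →
distance 1); this is a property of the definition, not a bug.

**Matching blocks** use the pure recursive Ratcliff/Obershelp decomposition:
find the longest common contiguous substring, recurse on the unmatched
prefixes and suffixes. No junk or popularity heuristics are applied (unlike
`difflib`'s default `autojunk`), so results are independent of input length
and fully reproducible; with heuristics disabled, `difflib` agrees exactly
and serves as a cross-check in the tests. Ties among equally long blocks go
to the smallest start position in the first string, then in the second.

**Token sort ratio** joins the sorted tokens with single spaces before
computing 2M/T. Two whitespace conventions exist in the wild: the reference
tools count the joining spaces toward M and T (the package default,
`whitespace="include"`), while the published worked arithmetic for the
sentence example excludes them (`whitespace="exclude"`, M = 16, T = 40).
Both modes give 80 on that example and identical results on single-word
inputs; they can differ by a few points when word counts are unequal (the
test suite pins a diverging pair). An empty target or response scores 0.
Scores are computed in full precision; the CSV writer rounds half-up to an
integer by default (`--round float` disables), since the published tools
report integers.

## Batch scoring

The CSV contract: UTF-8, RFC 4180, header columns named exactly `target`
and `response`; all input columns, cell values and row order are preserved
and the requested metric columns (`TSR_score`, and optionally `LS_score`,
`Jaro_score`, `PWC_auto`) are appended, with numbered fresh names if a
column name is already taken. Errors are hard: missing required column,
ragged row, or undecodable bytes abort with the column/row named — silent
repair would corrupt scoring studies. Empty or missing responses are legal,
score TSR 0, and are counted in the run summary. A UTF-8 BOM is tolerated
on read and never written. Re-running on identical input is byte-identical.

The automated percent-words-correct (`PWC_auto`) is 100 × (multiset
intersection of target and response tokens) / (target token count). Multiset
(not set) intersection means a repeated target word must be reported each
time to earn credit. It counts all tokens, not content words only —
content-word protocols need language-specific knowledge this package
deliberately avoids — and credits only exact post-normalization matches; it
is therefore a strict automated reference, not a reproduction of tolerant
human scoring. An empty target makes the denominator undefined: the
function raises, and the batch scorer records NaN for that row instead of
aborting.

## Synthetic listener corpus

The human-scored listening datasets used to validate these metrics are not
redistributable, so evaluation runs on a seeded simulator whose ground truth
is known by construction. Each trial draws a target sentence of 5–20 words
(the typical length range of sentence-level intelligibility materials) from
a packaged 252-word neutral lexicon, then corrupts it:

| parameter | default | meaning |
|---|---|---|
| `report_prob` | 0.7 | per-word probability the listener reports the word |
| `typo_rate` | 0.05 | per-character probability of an adjacent-key substitution |
| `shuffle_prob` | 0.1 | probability the reported words are permuted |
| `intrusion_rate` | 0.1 | expected count (Poisson) of inserted extraneous words |

`true_report_fraction` = reported words / target words, fixed before typos
(a mistyped word was still reported). Keyboard adjacency defaults to QWERTY
horizontal + staggered-vertical neighbours (`t` → `r y f g`, reproducing the
`wayer`-for-`water` error) and is configurable for other layouts. Intrusions
are drawn from the lexicon excluding the target's own words so the ground
truth stays well defined. Random streams are spawned per record from the
master seed, making individual records independently reproducible.

The default evaluation corpus is 1000 records with each trial's
`report_prob` drawn uniformly from [0, 1] — emulating a study spanning the
full intelligibility range — with the default error rates above. Defaults
were fixed once, as plausible magnitudes for typed responses under noise;
they are free parameters of the simulation, not estimates of any real
dataset.

What the simulation does *not* model: phonological confusions, real word
frequencies, syntax-preserving paraphrase, or signal-to-noise manipulations.
Passing correlation gates on synthetic data therefore shows the pipeline's
internal consistency and the metrics' expected behaviour under these error
processes — not field validity on human data.

## Evaluation harness

Pearson correlations between each metric and a reference column are
pooled over trials (not averaged per participant — the simulator has no
participant structure). Expected signs: LS and J negative (distances),
TSR and PWC positive (similarities); the harness flags violations. A
constant metric or reference column makes the correlation undefined and
raises with the column named, never returning a silent zero. On the default
corpus the observed orderings are computed by the tests themselves (e.g.,
r(TSR, truth) ≥ 0.8; with all error processes disabled PWC_auto is an exact
linear function of the report fraction, so r = 1 to floating-point
precision). Headline correlations reported for real human-scored datasets
are not reproduced here because those data are not available; only the
methodology and direction claims are.

## Numerical choices

* Ratios are kept in double precision end to end; test comparisons use
  1e-9 absolute tolerance on unrounded values and exact equality on
  rounded ones.
* TSR integer rounding is half-up (80.5 → 81), not banker's.
* CSV floats are written with `%.6g`, integers bare, for byte-stable
  output.
* The evaluation corpus size (1000 records) and the oracle-comparison
  sample sizes (1000 Levenshtein pairs ≤ 12 chars, 500 Jaro pairs ≤ 8,
  500 block decompositions ≤ 15) keep the full suite in the tens of
  seconds while exhausting the short-string space densely.

## Known limitations

* Orthographic only: `eye` for `I` scores poorly despite the perfect
  phonological match; pronunciation-dictionary alignment is out of scope.
* TSR overestimates accuracy for near-zero-overlap responses that share
  stray characters with the target.
* No spelling correction or grammatical normalization is applied, by
  design: such rules are language-specific.
* `PWC_auto` is stricter than human percent-words-correct scoring, which
  typically tolerates misspellings.
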