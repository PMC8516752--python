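# transcriptscore

Fuzzy string-matching metrics for automated scoring of listener transcripts
in speech intelligibility research.

## The problem

Speech intelligibility studies routinely ask listeners to type out what they
heard ("type out what you hear") and express the intelligibility of each
stimulus as the percentage of target words correctly reported (PWC). Scoring
thousands of raw typed responses by hand is slow, and human scoring protocols
vary. Exact-match automated scorers are fast but count every misspelling as
wrong: the typo `wayer` for `water` ([Y] sits next to [T]) earns zero credit
despite being orthographically almost right.

Fuzzy (approximate) string matching scores the *degree* of orthographic match
between a response and its target instead of demanding exact equality. This
package implements, from scratch, the three metrics relevant to transcript
scoring, plus preprocessing, batch CSV scoring, a synthetic listener-response
simulator, and an evaluation harness:

* **Levenshtein distance (LS)** — the minimum number of single-character
  insertions, deletions, and substitutions converting the response into the
  target. `levenshtein("water", "wayer") = 1`; for target
  *"The big blue house is for sale"* and response *"sail"* it is 27.
  Unbounded; lower is better.
* **Jaro distance (J)** — `1 − (1/3)(s/A + s/B + (s−n)/s)`, where *A*, *B*
  are the string lengths, *s* the number of matching characters whose
  positions differ by at most `⌊max(A,B)/2⌋ − 1`, and *n* the transpositions
  among them. Bounded in [0, 1]; 0 = identical, 1 = no matching characters.
* **Token sort ratio (TSR)** — sort each string's words alphabetically, then
  score `2M/T × 100`, where *M* is the total length of the shared substrings
  found by recursive longest-common-substring decomposition and *T* the
  summed length of both strings. Bounded in [0, 100]; word order is ignored
  by design, so *"John saw Mary"* scores 100 against *"Mary saw John"*.

All metrics operate on normalized text: punctuation removed, whitespace
collapsed, characters case-folded. Normalization is Unicode-category based,
so any orthography representable in UTF-8 works.

## Worked example

Score one target/response pair from the command line:

```sh
$ transcriptscore pair "The big blue house is for sale" "the hous is for sale"
TSR_score: 80
LS_score: 10
Jaro_score: 0.244444
PWC_auto: 57.1429
```

The TSR of 80 comes from sorting both strings' tokens
(`big blue for house is sale the` vs. `for hous is sale the`) and finding the
shared substrings `for hous` and `is sale the`: not counting whitespace,
M = 16 shared characters out of T = 40 total, and 2·16/40·100 = 80. The
Levenshtein distance counts 10 character edits, and the automated
percent-words-correct credits the 4 exactly-matching words out of 7 (57.1).

Batch scoring follows the standard CSV contract — columns named `target`
and `response` in, everything preserved plus a `TSR_score` column out:

```sh
$ transcriptscore score responses.csv scored.csv
scored 2/2 rows (0 empty responses) -> scored.csv
$ cat scored.csv
target,response,TSR_score
water,wayer,80
The big blue house is for sale,the hous is for sale,80
```

The same operations are available as library functions:

```python
from transcriptscore import token_sort_ratio, levenshtein, jaro_distance
token_sort_ratio("water", "wayer")   # 80.0
levenshtein("water", "wayer")        # 1
round(jaro_distance("water", "wayer"), 3)  # 0.133
```

`transcriptscore simulate` writes a seeded synthetic corpus of
target/response pairs with a known ground-truth report fraction, and
`transcriptscore evaluate` correlates every metric against that ground truth
(Pearson's *r*), checking that distances correlate negatively and ratios
positively with accuracy. See `docs/methods.md` for the simulation model and
all numerical conventions.

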