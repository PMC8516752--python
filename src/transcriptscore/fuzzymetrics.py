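"""From-scratch fuzzy string-matching metrics for transcript scoring.

Three metrics quantify the orthographic match between a target sentence and a
listener's typed response:

* **Levenshtein distance** — minimum number of single-character insertions,
  deletions, and substitutions converting the response into the target.
  Unbounded; 0 means identical.
* **Jaro distance** — ``1 - (1/3) * (s/A + s/B + (s - n)/s)`` where ``A`` and
  ``B`` are the string lengths, ``s`` the number of matching characters under
  a positional window, and ``n`` the number of transpositions among them.
  Bounded in [0, 1]; 0 means identical, 1 means no matching characters.
  Two identical characters only count as a match if their positions differ by
  at most ``floor(max(A, B) / 2) - 1`` (clamped at zero).
* **Token sort ratio (TSR)** — sort each string's words alphabetically, join
  with single spaces, then score ``2 * M / T * 100`` where ``M`` is the
  summed length of the shared substrings found by recursive
  longest-common-substring decomposition (Ratcliff/Obershelp) and ``T`` the
  summed length of both strings.  Bounded in [0, 100]; word order is
  deliberately ignored, so a response that permutes the target's words scores
  100.

All metrics treat spaces as ordinary characters and expect normalized input
(see :mod:`transcriptscore.textnorm`); :func:`token_sort_ratio` normalizes
raw strings itself for convenience.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

from .textnorm import (
    DEFAULT_RULES,
    NormalizationRules,
    NormalizedText,
    as_normalized,
    sort_tokens,
)

__all__ = [
    "JaroComponents",
    "MatchBlock",
    "RatioComponents",
    "levenshtein",
    "match_window",
    "jaro_components",
    "jaro_distance",
    "matching_blocks",
    "ratio_components",
    "sequence_ratio",
    "token_sort_ratio",
    "round_half_up",
]


# ---------------------------------------------------------------------------
# Levenshtein distance
# ---------------------------------------------------------------------------


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance between ``a`` and ``b``.

    Symmetric; 0 iff the strings are equal.  Spaces count as ordinary
    characters, so for sentence inputs the distance includes the edits on the
    separators.
    """
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    # two-row dynamic programme over the edit lattice
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


# ---------------------------------------------------------------------------
# Jaro distance
# ---------------------------------------------------------------------------


def match_window(len_a: int, len_b: int) -> int:
    """Maximum positional separation for two characters to count as a match.

    ``max(0, floor(max(len_a, len_b) / 2) - 1)``: half the longer string's
    length, minus one, never negative.
    """
    return max(0, max(len_a, len_b) // 2 - 1)


@dataclass(frozen=True)
class JaroComponents:
    """The quantities entering the Jaro formula for one string pair.

    ``target_len`` (A) and ``response_len`` (B) are character counts;
    ``matches`` (s) is the number of within-window matching characters;
    ``transpositions`` (n) is half the number of matched positions whose
    order differs between the two matched sequences, rounded down.
    """

    target_len: int
    response_len: int
    matches: int
    transpositions: int
    window: int


def jaro_components(a: str, b: str) -> JaroComponents:
    """Greedy within-window character matching between ``a`` and ``b``.

    Scanning ``b`` left to right, each character is matched to the leftmost
    not-yet-matched identical character of ``a`` whose position is within the
    window.  Transpositions are counted on the two matched subsequences read
    off in their natural orders.
    """
    window = match_window(len(a), len(b))
    a_used = [False] * len(a)
    b_used = [False] * len(b)
    for j, cb in enumerate(b):
        lo = max(0, j - window)
        hi = min(len(a), j + window + 1)
        for i in range(lo, hi):
            if not a_used[i] and a[i] == cb:
                a_used[i] = True
                b_used[j] = True
                break
    a_seq = [a[i] for i in range(len(a)) if a_used[i]]
    b_seq = [b[j] for j in range(len(b)) if b_used[j]]
    s = len(a_seq)
    n = sum(ca != cb for ca, cb in zip(a_seq, b_seq)) // 2
    return JaroComponents(len(a), len(b), s, n, window)


def jaro_distance(a: str, b: str) -> float:
    """Jaro distance in [0, 1]; 0 for identical strings, 1 for disjoint ones.

    Empty-string convention: two empty strings are identical (0); one empty
    string shares no characters with anything (1).
    """
    if not a and not b:
        return 0.0
    if not a or not b:
        return 1.0
    comp = jaro_components(a, b)
    s = comp.matches
    if s == 0:
        return 1.0
    sim = (
        s / comp.target_len + s / comp.response_len + (s - comp.transpositions) / s
    ) / 3.0
    return 1.0 - sim


# ---------------------------------------------------------------------------
# Matching blocks and sequence ratio (Ratcliff/Obershelp)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MatchBlock:
    """One shared substring: start positions in both strings and its length."""

    pos_target: int
    pos_response: int
    length: int


def _longest_block(
    a: str, b: str, alo: int, ahi: int, blo: int, bhi: int
) -> tuple[int, int, int]:
    """Longest common substring of a[alo:ahi] and b[blo:bhi].

    Ties broken by smallest start in ``a``, then smallest start in ``b``
    (achieved by the strict ``>`` update over ascending scan order).
    """
    b_index: dict[str, list[int]] = {}
    for j in range(blo, bhi):
        b_index.setdefault(b[j], []).append(j)
    best_i, best_j, best_size = alo, blo, 0
    j2len: dict[int, int] = {}
    for i in range(alo, ahi):
        new_j2len: dict[int, int] = {}
        for j in b_index.get(a[i], ()):
            k = j2len.get(j - 1, 0) + 1
            new_j2len[j] = k
            if k > best_size:
                best_i, best_j, best_size = i - k + 1, j - k + 1, k
        j2len = new_j2len
    return best_i, best_j, best_size


def _blocks(a: str, b: str, alo: int, ahi: int, blo: int, bhi: int) -> Iterator[MatchBlock]:
    i, j, k = _longest_block(a, b, alo, ahi, blo, bhi)
    if k == 0:
        return
    yield from _blocks(a, b, alo, i, blo, j)
    yield MatchBlock(i, j, k)
    yield from _blocks(a, b, i + k, ahi, j + k, bhi)


def matching_blocks(a: str, b: str) -> list[MatchBlock]:
    """Recursive longest-matching-block decomposition of two strings.

    Finds the longest common contiguous substring, then recurses on the
    unmatched prefixes and suffixes.  The returned blocks are ordered,
    non-overlapping, and strictly increasing in both coordinates; their
    summed length is the ``M`` of the sequence ratio.  No junk or popularity
    heuristics are applied, so the decomposition is independent of input
    size and fully reproducible.
    """
    return list(_blocks(a, b, 0, len(a), 0, len(b)))


@dataclass(frozen=True)
class RatioComponents:
    """``M`` (summed shared-substring length) and ``T`` (summed string length)."""

    M: int
    T: int


def ratio_components(a: str, b: str, count_whitespace: bool = True) -> RatioComponents:
    """Compute M and T for the pair, optionally excluding whitespace.

    With ``count_whitespace=False`` the blocks are still found on the full
    strings (spaces included), but only non-whitespace characters contribute
    to M and T.
    """
    blocks = matching_blocks(a, b)
    if count_whitespace:
        m = sum(bl.length for bl in blocks)
        t = len(a) + len(b)
    else:
        m = sum(
            1
            for bl in blocks
            for ch in a[bl.pos_target : bl.pos_target + bl.length]
            if not ch.isspace()
        )
        t = sum(1 for ch in a if not ch.isspace()) + sum(
            1 for ch in b if not ch.isspace()
        )
    return RatioComponents(m, t)


def sequence_ratio(a: str, b: str) -> float:
    """``2 * M / T`` in [0, 1]; 1 iff the strings are equal.

    Two empty strings are equal, hence ratio 1.
    """
    comp = ratio_components(a, b)
    if comp.T == 0:
        return 1.0
    return 2.0 * comp.M / comp.T


# ---------------------------------------------------------------------------
# Token sort ratio
# ---------------------------------------------------------------------------


def token_sort_ratio(
    target: str | NormalizedText,
    response: str | NormalizedText,
    *,
    whitespace: str = "include",
    rules: NormalizationRules = DEFAULT_RULES,
) -> float:
    """Token sort ratio in [0, 100] between a target and a response.

    Each input is normalized (if given raw), its tokens sorted
    alphabetically and re-joined with single spaces, and the sequence ratio
    of the two sorted strings is scaled to 0-100.  Scores 100 iff the sorted
    token strings are identical — in particular for any word-order
    permutation of the target — and 0 whenever either input is empty.

    ``whitespace`` selects whether the joining spaces between sorted tokens
    count toward M and T: ``"include"`` (default, the reference-tool
    behaviour) or ``"exclude"``.  Both modes agree on single-word inputs and
    on the canonical examples; they can differ slightly on sentence pairs
    with unequal word counts.
    """
    if whitespace not in ("include", "exclude"):
        raise ValueError(f"whitespace must be 'include' or 'exclude', got {whitespace!r}")
    t = as_normalized(target, rules)
    r = as_normalized(response, rules)
    if not t.tokens or not r.tokens:
        return 0.0
    ts = sort_tokens(t).text
    rs = sort_tokens(r).text
    comp = ratio_components(ts, rs, count_whitespace=(whitespace == "include"))
    return 200.0 * comp.M / comp.T


def round_half_up(x: float) -> int:
    """Round a non-negative score half-up to an integer (80.5 -> 81)."""
    return int(math.floor(x + 0.5))
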