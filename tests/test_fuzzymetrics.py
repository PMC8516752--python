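"""The three metrics against worked examples, independent oracles, and their
defining invariants."""

import difflib
import functools
import itertools
import random

import edlib
import pytest
from hypothesis import given
from hypothesis import strategies as st

from transcriptscore import (
    jaro_components,
    jaro_distance,
    levenshtein,
    match_window,
    matching_blocks,
    normalize,
    ratio_components,
    sequence_ratio,
    token_sort_ratio,
)

SENTENCE = "the big blue house is for sale"

short = st.text(alphabet="ab c", max_size=10)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def levenshtein_oracle(a: str, b: str) -> int:
    """Memoized recursive edit distance, structurally unlike the DP loop."""

    @functools.lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        return min(
            rec(i - 1, j) + 1,
            rec(i, j - 1) + 1,
            rec(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
        )

    return rec(len(a), len(b))


def max_window_matches(a: str, b: str) -> int:
    """Brute-force maximal within-window matching (bitmask search over all
    legal assignments), the defining value of the Jaro s."""
    w = match_window(len(a), len(b))

    @functools.lru_cache(maxsize=None)
    def rec(j: int, used: int) -> int:
        if j == len(b):
            return 0
        best = rec(j + 1, used)
        for i in range(max(0, j - w), min(len(a), j + w + 1)):
            if not used >> i & 1 and a[i] == b[j]:
                best = max(best, 1 + rec(j + 1, used | 1 << i))
        return best

    return rec(0, 0)


def longest_common_substring_len(a: str, b: str) -> int:
    best = 0
    for i in range(len(a)):
        for j in range(len(b)):
            k = 0
            while i + k < len(a) and j + k < len(b) and a[i + k] == b[j + k]:
                k += 1
            best = max(best, k)
    return best


def random_string(rng: random.Random, max_len: int, alphabet: str = "abc d") -> str:
    return "".join(rng.choice(alphabet) for _ in range(rng.randint(0, max_len)))


# ---------------------------------------------------------------------------
# Levenshtein
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ("water", "wayer", 1),
        (SENTENCE, "sail", 27),
        ("abc", "", 3),
        ("", "", 0),
        ("abc", "acb", 2),
    ],
)
def test_levenshtein_examples(a, b, expected):
    assert levenshtein(a, b) == expected


def test_levenshtein_against_oracles():
    rng = random.Random(42)
    for _ in range(300):
        a, b = random_string(rng, 12), random_string(rng, 12)
        d = levenshtein(a, b)
        assert d == levenshtein_oracle(a, b)
        assert d == edlib.align(a, b)["editDistance"]


def test_levenshtein_exhaustive_short_edit_scripts():
    # every string within <=2 edits of "abc" over {a,b,c} must score <=2
    base = "abc"
    alphabet = "abc"
    reachable = {base: 0}
    frontier = {base}
    for depth in (1, 2):
        new = set()
        for s in frontier:
            for i in range(len(s) + 1):
                for ch in alphabet:
                    new.add(s[:i] + ch + s[i:])  # insertion
            for i in range(len(s)):
                new.add(s[:i] + s[i + 1 :])  # deletion
                for ch in alphabet:
                    new.add(s[:i] + ch + s[i + 1 :])  # substitution
        for s in new:
            reachable.setdefault(s, depth)
        frontier = new
    for s, depth in reachable.items():
        assert levenshtein(base, s) <= depth


@given(short, short, short)
def test_levenshtein_metric_axioms(a, b, c):
    assert levenshtein(a, b) == levenshtein(b, a)
    assert (levenshtein(a, b) == 0) == (a == b)
    assert levenshtein(a, c) <= levenshtein(a, b) + levenshtein(b, c)


# ---------------------------------------------------------------------------
# Jaro
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "la, lb, expected",
    [(30, 4, 14), (5, 5, 1), (1, 1, 0), (0, 0, 0), (2, 2, 0)],
)
def test_match_window(la, lb, expected):
    assert match_window(la, lb) == expected


def test_jaro_components_worked_examples():
    comp = jaro_components("water", "wayer")
    assert (comp.target_len, comp.response_len) == (5, 5)
    assert (comp.matches, comp.transpositions) == (4, 0)

    comp = jaro_components(SENTENCE, "sail")
    assert (comp.target_len, comp.response_len) == (30, 4)
    # only "i" (target pos 6) and "l" (target pos 10) fall within the
    # 14-character window; the "sa" of "sale" is too far right to match
    assert (comp.matches, comp.transpositions) == (2, 0)


def test_jaro_transpositions_on_swapped_prefix():
    comp = jaro_components("abcd", "bacd")
    assert (comp.matches, comp.transpositions) == (4, 1)


def test_jaro_window_forbids_adjacent_swap_in_two_char_strings():
    # window = max(0, 2//2 - 1) = 0: the swapped characters sit one position
    # apart, so nothing matches and the strings count as disjoint
    comp = jaro_components("ab", "ba")
    assert comp.window == 0
    assert comp.matches == 0
    assert jaro_distance("ab", "ba") == 1.0


@pytest.mark.parametrize(
    "a, b, expected_3dp",
    [
        ("water", "wayer", 0.133),
        (SENTENCE, "sail", 0.478),
        ("water", "water", 0.0),
        ("abc", "xyz", 1.0),
    ],
)
def test_jaro_distance_examples(a, b, expected_3dp):
    assert round(jaro_distance(a, b), 3) == expected_3dp


def test_jaro_empty_string_convention():
    assert jaro_distance("", "") == 0.0
    assert jaro_distance("water", "") == 1.0
    assert jaro_distance("", "water") == 1.0


def test_jaro_matches_bruteforce_maximal_matching():
    rng = random.Random(7)
    for _ in range(200):
        a, b = random_string(rng, 8), random_string(rng, 8)
        assert jaro_components(a, b).matches == max_window_matches(a, b)


@given(short, short)
def test_jaro_bounds_and_symmetry(a, b):
    d = jaro_distance(a, b)
    assert 0.0 <= d <= 1.0
    assert d == jaro_distance(b, a)
    if a and a == b:
        assert d == 0.0


# ---------------------------------------------------------------------------
# matching blocks / sequence ratio
# ---------------------------------------------------------------------------


def test_matching_blocks_worked_example_both_whitespace_modes():
    a = "big blue for house is sale the"
    b = "for hous is sale the"
    incl = ratio_components(a, b, count_whitespace=True)
    excl = ratio_components(a, b, count_whitespace=False)
    assert (incl.M, incl.T) == (20, 50)
    assert (excl.M, excl.T) == (16, 40)
    # the two shared substrings, spaces inside blocks kept
    texts = [a[bl.pos_target : bl.pos_target + bl.length] for bl in matching_blocks(a, b)]
    assert texts == ["for hous", " is sale the"]


def test_matching_blocks_identity_and_disjoint():
    blocks = matching_blocks("water", "water")
    assert len(blocks) == 1 and blocks[0].length == 5
    assert matching_blocks("abc", "xyz") == []


def test_first_block_is_longest_common_substring():
    rng = random.Random(3)
    for _ in range(200):
        a, b = random_string(rng, 15), random_string(rng, 15)
        blocks = matching_blocks(a, b)
        best = longest_common_substring_len(a, b)
        if best == 0:
            assert blocks == []
        else:
            assert max(bl.length for bl in blocks) == best


def test_blocks_are_common_substrings_monotone_and_disjoint():
    rng = random.Random(4)
    for _ in range(200):
        a, b = random_string(rng, 15), random_string(rng, 15)
        blocks = matching_blocks(a, b)
        prev_a = prev_b = -1
        for bl in blocks:
            assert bl.length >= 1
            assert (
                a[bl.pos_target : bl.pos_target + bl.length]
                == b[bl.pos_response : bl.pos_response + bl.length]
            )
            assert bl.pos_target > prev_a and bl.pos_response > prev_b
            prev_a = bl.pos_target + bl.length - 1
            prev_b = bl.pos_response + bl.length - 1


def test_blocks_and_ratio_agree_with_difflib():
    rng = random.Random(5)
    for _ in range(200):
        a, b = random_string(rng, 15), random_string(rng, 15)
        sm = difflib.SequenceMatcher(None, a, b, autojunk=False)
        ours = [(bl.pos_target, bl.pos_response, bl.length) for bl in matching_blocks(a, b)]
        theirs = [(m.a, m.b, m.size) for m in sm.get_matching_blocks()[:-1]]
        assert ours == theirs
        if a or b:
            assert sequence_ratio(a, b) == pytest.approx(sm.ratio(), abs=1e-12)


@pytest.mark.parametrize(
    "a, b, expected",
    [("water", "wayer", 0.8), ("abc", "abc", 1.0), ("abc", "xyz", 0.0)],
)
def test_sequence_ratio_examples(a, b, expected):
    assert sequence_ratio(a, b) == pytest.approx(expected, abs=1e-12)
    comp = ratio_components(a, b)
    assert 2 * comp.M <= comp.T


# ---------------------------------------------------------------------------
# token sort ratio
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("mode", ["include", "exclude"])
@pytest.mark.parametrize(
    "target, response, expected",
    [
        ("water", "wayer", 80.0),
        ("The big blue house is for sale", "the hous is for sale", 80.0),
        ("mary saw john", "john saw mary", 100.0),
        ("water", "", 0.0),
        ("", "water", 0.0),
        ("", "", 0.0),
    ],
)
def test_token_sort_ratio_examples(target, response, expected, mode):
    assert token_sort_ratio(target, response, whitespace=mode) == pytest.approx(
        expected, abs=1e-9
    )


def test_whitespace_modes_can_diverge_on_unequal_word_counts():
    # same shared characters, different space bookkeeping
    incl = token_sort_ratio("aa bb cc", "aa", whitespace="include")
    excl = token_sort_ratio("aa bb cc", "aa", whitespace="exclude")
    assert incl != excl
    # include mode: M=2, T=10; exclude mode: M=2, T=8
    assert incl == pytest.approx(40.0, abs=1e-9)
    assert excl == pytest.approx(50.0, abs=1e-9)


def test_token_sort_ratio_rejects_unknown_mode():
    with pytest.raises(ValueError):
        token_sort_ratio("a", "b", whitespace="maybe")


@given(
    st.lists(st.text(alphabet="abc", min_size=1, max_size=4), min_size=1, max_size=6),
    st.lists(st.text(alphabet="abc", min_size=1, max_size=4), min_size=1, max_size=6),
    st.randoms(use_true_random=False),
)
def test_token_sort_ratio_permutation_invariance_and_bounds(t_toks, r_toks, rnd):
    target = " ".join(t_toks)
    response = " ".join(r_toks)
    score = token_sort_ratio(target, response)
    assert 0.0 <= score <= 100.0
    t_perm = list(t_toks)
    r_perm = list(r_toks)
    rnd.shuffle(t_perm)
    rnd.shuffle(r_perm)
    assert token_sort_ratio(" ".join(t_perm), " ".join(r_perm)) == pytest.approx(
        score, abs=1e-9
    )


@given(st.lists(st.text(alphabet="ab", min_size=1, max_size=4), min_size=1, max_size=6))
def test_token_sort_ratio_identity(tokens):
    s = " ".join(tokens)
    assert token_sort_ratio(s, s) == pytest.approx(100.0, abs=1e-12)


def test_deleting_a_response_token_never_increases_shared_length():
    from transcriptscore import sort_tokens

    target = normalize("the big blue house is for sale")
    response_tokens = ["the", "hous", "is", "for", "sale"]
    ts = sort_tokens(target).text

    def shared(tokens):
        rs = sort_tokens(normalize(" ".join(tokens))).text
        return ratio_components(ts, rs).M

    full = shared(response_tokens)
    for i in range(len(response_tokens)):
        reduced = response_tokens[:i] + response_tokens[i + 1 :]
        assert shared(reduced) <= full
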