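"""Orthographic preprocessing of target sentences and listener responses.

Every fuzzy metric in this package operates on a canonical normalized form of
the input string: case-folded, punctuation-stripped, whitespace-collapsed.
Transcription tasks ("type out what you hear") produce responses with
arbitrary capitalization, stray punctuation and uneven spacing, none of which
carries information about which words the listener identified, so the scorer
removes them before any character-level comparison.

Normalization is deliberately language-agnostic: the punctuation set is
defined by Unicode general categories (P* and S*) rather than an ASCII list,
case folding is full Unicode case folding, and tokenization splits on any
Unicode whitespace.  The metrics therefore apply to any orthography a UTF-8
string can hold.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass

__all__ = [
    "NormalizationRules",
    "NormalizedText",
    "DEFAULT_RULES",
    "normalize",
    "sort_tokens",
    "as_normalized",
]

#: Characters treated as word separators when removed (dash/connector
#: punctuation plus slashes): "blue-green" must become two tokens, not
#: "bluegreen".  All other punctuation/symbol characters are deleted in place
#: ("it's" -> "its").
_SLASHES = frozenset("/\\")


@dataclass(frozen=True)
class NormalizationRules:
    """Configuration of the preprocessing pipeline.

    Parameters
    ----------
    lowercase:
        Apply full Unicode case folding (default True).
    strip_punctuation:
        Remove characters in Unicode categories P* (punctuation) and
        S* (symbols) (default True).
    separate_dashes:
        When stripping punctuation, replace dash/connector punctuation and
        slashes with a space instead of deleting them, so hyphenated
        compounds keep their word boundary (default True).
    """

    lowercase: bool = True
    strip_punctuation: bool = True
    separate_dashes: bool = True


DEFAULT_RULES = NormalizationRules()


@dataclass(frozen=True)
class NormalizedText:
    """A preprocessed string together with its token sequence.

    ``text`` is lowercase, free of punctuation, and single-space separated;
    ``tokens`` is the ordered tuple of its non-empty words.  Joining the
    tokens with single spaces reproduces ``text`` exactly, and normalizing
    ``text`` again is the identity.
    """

    text: str
    tokens: tuple[str, ...]

    def __bool__(self) -> bool:
        return bool(self.tokens)


def _strippable(ch: str) -> bool:
    return unicodedata.category(ch)[0] in "PS"


def _is_separator(ch: str) -> bool:
    return unicodedata.category(ch) in ("Pd", "Pc") or ch in _SLASHES


def normalize(raw: str, rules: NormalizationRules = DEFAULT_RULES) -> NormalizedText:
    """Normalize a raw orthographic string.

    A total function: any Unicode string (including the empty string, or one
    consisting only of punctuation/whitespace) is accepted; the latter two
    normalize to the empty ``NormalizedText``.

    >>> normalize("  Water,   please!! ").text
    'water please'
    """
    s = raw.casefold() if rules.lowercase else raw
    if rules.strip_punctuation:
        out = []
        for ch in s:
            if _strippable(ch):
                if rules.separate_dashes and _is_separator(ch):
                    out.append(" ")
                # apostrophes and all other punctuation: deleted in place
            else:
                out.append(ch)
        s = "".join(out)
    tokens = tuple(s.split())
    return NormalizedText(" ".join(tokens), tokens)


def sort_tokens(t: NormalizedText) -> NormalizedText:
    """Return ``t`` with its tokens sorted lexicographically by code point.

    The token multiset is preserved (duplicates kept); sorting is stable for
    equal keys.  This is the first step of the token sort ratio, and only
    affects multi-word strings.
    """
    toks = tuple(sorted(t.tokens))
    return NormalizedText(" ".join(toks), toks)


def as_normalized(
    x: str | NormalizedText, rules: NormalizationRules = DEFAULT_RULES
) -> NormalizedText:
    """Coerce a raw string to :class:`NormalizedText`; pass one through."""
    if isinstance(x, NormalizedText):
        return x
    return normalize(x, rules)
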