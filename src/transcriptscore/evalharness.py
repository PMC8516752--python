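"""Evaluation harness: automated word-overlap reference score and metric
correlations.

Validating an automated transcript metric means checking how well it tracks a
reference accuracy score across a corpus of trials.  This module provides the
two pieces needed at desk scale: an automated percentage-words-correct
reference (exact multiset word overlap between target and response) and
Pearson correlations of each metric against a reference column, with the
expected correlation signs checked (edit-type distances should correlate
negatively with accuracy; similarity ratios positively).
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .textnorm import NormalizedText, as_normalized

__all__ = [
    "EXPECTED_SIGNS",
    "word_overlap_pwc",
    "pearson_r",
    "evaluate_metrics",
    "score_corpus",
]

#: Expected direction of each metric's correlation with a reference accuracy
#: score: distances fall as accuracy rises, ratios rise with it.
EXPECTED_SIGNS: dict[str, str] = {
    "LS_score": "-",
    "Jaro_score": "-",
    "TSR_score": "+",
    "PWC_auto": "+",
}


def word_overlap_pwc(
    target: str | NormalizedText, response: str | NormalizedText
) -> float:
    """Automated percentage words correct by exact multiset word overlap.

    100 times the multiset intersection of target and response tokens divided
    by the target token count.  Order-free and capped at 100 by construction;
    repeated target words must each be reported to earn credit.  Words only
    count when spelled identically after normalization — the tolerant
    "allowing for misspellings" judgment of a human scorer is exactly what
    this automated variant does not attempt.

    Raises ``ValueError`` for an empty target (undefined denominator).
    """
    t = as_normalized(target)
    r = as_normalized(response)
    if not t.tokens:
        raise ValueError("word_overlap_pwc: empty target has no words to score")
    shared = Counter(t.tokens) & Counter(r.tokens)
    return 100.0 * sum(shared.values()) / len(t.tokens)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation, with explicit errors on degenerate input.

    Requires equal lengths of at least 3 and non-constant sequences; a
    constant input makes the correlation undefined and raises ``ValueError``
    rather than silently returning 0 or NaN.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("pearson_r: inputs must be equal-length 1-d sequences")
    if xa.size < 3:
        raise ValueError(f"pearson_r: need at least 3 observations, got {xa.size}")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise ValueError("pearson_r: correlation undefined for constant input")
    return float(stats.pearsonr(xa, ya).statistic)


def score_corpus(records: Iterable, **config) -> pd.DataFrame:
    """Score simulated corpus records with all metrics.

    Takes an iterable of :class:`~transcriptscore.synthcorpus.CorpusRecord`
    (or any object with ``target``/``response`` attributes) and returns a
    data frame with the four metric columns plus any ground-truth columns
    the records carry (``true_report_fraction``, ``n_typos``).
    """
    from .batchscore import ScoringConfig, score_pair  # avoid import cycle

    cfg = ScoringConfig(**config) if config else ScoringConfig()
    rows = []
    for i, rec in enumerate(records):
        sr = score_pair(rec.target, rec.response, cfg, row_id=i)
        row = {
            "target": rec.target,
            "response": rec.response,
            "LS_score": sr.levenshtein,
            "Jaro_score": sr.jaro,
            "TSR_score": sr.tsr,
            "PWC_auto": sr.pwc_auto,
        }
        for extra in ("true_report_fraction", "n_typos"):
            if hasattr(rec, extra):
                row[extra] = getattr(rec, extra)
        rows.append(row)
    return pd.DataFrame(rows)


def evaluate_metrics(
    scored: pd.DataFrame, reference: str = "true_report_fraction"
) -> pd.DataFrame:
    """Correlate each metric column with the reference column.

    Returns a table with one row per metric present in ``scored``:
    ``metric``, ``r`` (Pearson), ``n``, ``expected_sign`` and ``sign_ok``
    (whether the observed sign matches the expected direction).  Degenerate
    (constant) columns raise with the offending column named.
    """
    if reference not in scored.columns:
        raise ValueError(f"reference column {reference!r} not in data")
    ref = scored[reference].to_numpy(dtype=float)
    rows = []
    for metric, sign in EXPECTED_SIGNS.items():
        if metric not in scored.columns:
            continue
        vals = scored[metric].to_numpy(dtype=float)
        try:
            r = pearson_r(vals, ref)
        except ValueError as err:
            raise ValueError(f"{metric}: {err}") from err
        rows.append(
            {
                "metric": metric,
                "r": r,
                "n": len(vals),
                "expected_sign": sign,
                "sign_ok": (r > 0) == (sign == "+"),
            }
        )
    if not rows:
        raise ValueError("no metric columns found in data")
    return pd.DataFrame(rows)
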