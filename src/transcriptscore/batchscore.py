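"""CSV batch scoring and command-line interface.

The file contract mirrors the published scoring tools for listener
transcripts: the input is a UTF-8 CSV with a header containing at least the
columns ``target`` and ``response``; the output is the same file with the
requested metric columns appended (at minimum ``TSR_score``, the token sort
ratio between 0 and 100).  All input columns, cell contents and row order
are preserved verbatim, and re-running on the same input is byte-identical.

Errors are hard and loud: a missing required column, undecodable bytes, or a
ragged row abort the run with a message naming the column or row — no silent
repair.  Missing or empty response cells are legal and score 0 (an empty
response shares nothing with the target); their count is reported in the run
summary.
"""

from __future__ import annotations

import csv
import io
import sys
from dataclasses import dataclass, field
from pathlib import Path

import click

from . import synthcorpus
from .evalharness import evaluate_metrics, score_corpus, word_overlap_pwc
from .fuzzymetrics import jaro_distance, levenshtein, round_half_up, token_sort_ratio
from .textnorm import DEFAULT_RULES, NormalizationRules, NormalizedText, normalize

__all__ = [
    "ScoringConfig",
    "ScoreRecord",
    "RunSummary",
    "BatchScoreError",
    "ALL_METRICS",
    "score_pair",
    "score_file",
    "cli",
]


class BatchScoreError(ValueError):
    """Hard error in the CSV scoring contract (bad column, row, or bytes)."""


#: Metric keys in output-column order, with their CSV column names.
ALL_METRICS: dict[str, str] = {
    "tsr": "TSR_score",
    "levenshtein": "LS_score",
    "jaro": "Jaro_score",
    "pwc": "PWC_auto",
}


@dataclass(frozen=True)
class ScoringConfig:
    """What to compute and how to report it.

    ``metrics`` selects the columns appended to a scored file (``tsr`` is
    the published tool's minimum); ``whitespace_mode`` picks whether joining
    spaces count in the token sort ratio; ``rounding`` is ``"int"``
    (half-up, the reference tool reports integers) or ``"float"``;
    ``rules`` configures normalization.
    """

    metrics: tuple[str, ...] = ("tsr",)
    whitespace_mode: str = "include"
    rounding: str = "int"
    rules: NormalizationRules = field(default_factory=lambda: DEFAULT_RULES)

    def __post_init__(self) -> None:
        bad = [m for m in self.metrics if m not in ALL_METRICS]
        if bad:
            raise ValueError(f"unknown metrics {bad}; choose from {list(ALL_METRICS)}")
        if self.rounding not in ("int", "float"):
            raise ValueError("rounding must be 'int' or 'float'")


@dataclass(frozen=True)
class ScoreRecord:
    """One scored target/response pair with all metric values."""

    row_id: int
    target_raw: str
    response_raw: str
    target_norm: NormalizedText
    response_norm: NormalizedText
    tsr: float
    levenshtein: int
    jaro: float
    pwc_auto: float


@dataclass
class RunSummary:
    rows_read: int = 0
    rows_scored: int = 0
    empty_responses: int = 0
    failures: int = 0


def score_pair(
    target: str,
    response: str,
    config: ScoringConfig = ScoringConfig(),
    row_id: int = 0,
) -> ScoreRecord:
    """Normalize once, then compute every metric on the normalized forms.

    The automated percent-words-correct is undefined for an empty target and
    reported as NaN there rather than raising, so degenerate rows do not
    abort a batch run.
    """
    t = normalize(target, config.rules)
    r = normalize(response, config.rules)
    tsr = token_sort_ratio(t, r, whitespace=config.whitespace_mode)
    if config.rounding == "int":
        tsr = float(round_half_up(tsr))
    pwc = word_overlap_pwc(t, r) if t.tokens else float("nan")
    return ScoreRecord(
        row_id=row_id,
        target_raw=target,
        response_raw=response,
        target_norm=t,
        response_norm=r,
        tsr=tsr,
        levenshtein=levenshtein(t.text, r.text),
        jaro=jaro_distance(t.text, r.text),
        pwc_auto=pwc,
    )


def _fresh_name(base: str, taken: set[str]) -> str:
    if base not in taken:
        return base
    k = 2
    while f"{base}_{k}" in taken:
        k += 1
    return f"{base}_{k}"


def _decode_lines(path: Path) -> list[str]:
    raw = path.read_bytes()
    if raw.startswith(b"\xef\xbb\xbf"):  # BOM tolerated on read, never written
        raw = raw[3:]
    lines = raw.split(b"\n")
    decoded = []
    for lineno, line in enumerate(lines, start=1):
        try:
            decoded.append(line.decode("utf-8"))
        except UnicodeDecodeError as err:
            raise BatchScoreError(
                f"{path}: undecodable UTF-8 bytes on line {lineno}: {err}"
            ) from err
    return decoded


def _fmt(value: float, rounding: str) -> str:
    if rounding == "int" or float(value).is_integer():
        return str(int(value))
    return format(value, ".6g")


def score_file(
    input_path: str | Path,
    output_path: str | Path,
    config: ScoringConfig = ScoringConfig(),
) -> RunSummary:
    """Score a CSV of target/response pairs, appending metric columns.

    The input must carry header columns named exactly ``target`` and
    ``response`` (extra columns are preserved untouched).  Output columns
    are named ``TSR_score``, ``LS_score``, ``Jaro_score``, ``PWC_auto``; if
    a name is already taken, a numbered fresh name is used so prior scores
    are never overwritten.
    """
    input_path = Path(input_path)
    output_path = Path(output_path)
    text = "\n".join(_decode_lines(input_path))
    rows = list(csv.reader(io.StringIO(text)))
    if not rows:
        raise BatchScoreError(f"{input_path}: empty file, no header row")
    header = rows[0]
    for col in ("target", "response"):
        if col not in header:
            raise BatchScoreError(
                f"{input_path}: required column {col!r} missing from header {header}"
            )
    t_idx = header.index("target")
    r_idx = header.index("response")

    summary = RunSummary()
    taken = set(header)
    out_cols = []
    for key in ALL_METRICS:
        if key in config.metrics:
            name = _fresh_name(ALL_METRICS[key], taken)
            taken.add(name)
            out_cols.append((key, name))

    out_rows = [header + [name for _, name in out_cols]]
    for rownum, row in enumerate(rows[1:], start=2):
        if not row:  # trailing blank line from final newline
            continue
        if len(row) != len(header):
            raise BatchScoreError(
                f"{input_path}: row {rownum} has {len(row)} cells, expected "
                f"{len(header)} (ragged rows are not repaired)"
            )
        summary.rows_read += 1
        target, response = row[t_idx], row[r_idx]
        if not response.strip():
            summary.empty_responses += 1
        rec = score_pair(target, response, config, row_id=rownum - 2)
        values = {
            "tsr": _fmt(rec.tsr, config.rounding),
            "levenshtein": str(rec.levenshtein),
            "jaro": format(rec.jaro, ".6g"),
            "pwc": format(rec.pwc_auto, ".6g"),
        }
        out_rows.append(row + [values[key] for key, _ in out_cols])
        summary.rows_scored += 1

    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerows(out_rows)
    output_path.write_text(buf.getvalue(), encoding="utf-8")
    return summary


# ---------------------------------------------------------------------------
# Command-line interface
# ---------------------------------------------------------------------------


def _config_from_flags(metrics, whitespace_mode, round_, keep_punctuation, no_lowercase):
    rules = NormalizationRules(
        lowercase=not no_lowercase, strip_punctuation=not keep_punctuation
    )
    return ScoringConfig(
        metrics=tuple(metrics), whitespace_mode=whitespace_mode,
        rounding=round_, rules=rules,
    )


@click.group()
def cli() -> None:
    """Fuzzy string-matching scorer for listener transcripts."""


_common = [
    click.option("--whitespace-mode", type=click.Choice(["include", "exclude"]),
                 default="include", show_default=True,
                 help="Count joining spaces in the token sort ratio."),
    click.option("--round", "round_", type=click.Choice(["int", "float"]),
                 default="int", show_default=True, help="TSR rounding."),
    click.option("--keep-punctuation", is_flag=True,
                 help="Skip punctuation removal during normalization."),
    click.option("--no-lowercase", is_flag=True, help="Skip case folding."),
]


def _add_options(opts):
    def wrap(f):
        for opt in reversed(opts):
            f = opt(f)
        return f
    return wrap


@cli.command()
@click.argument("target")
@click.argument("response")
@_add_options(_common)
def pair(target, response, whitespace_mode, round_, keep_punctuation, no_lowercase):
    """Score one TARGET/RESPONSE pair and print all metrics."""
    cfg = _config_from_flags(
        tuple(ALL_METRICS), whitespace_mode, round_, keep_punctuation, no_lowercase
    )
    rec = score_pair(target, response, cfg)
    click.echo(f"TSR_score: {_fmt(rec.tsr, cfg.rounding)}")
    click.echo(f"LS_score: {rec.levenshtein}")
    click.echo(f"Jaro_score: {rec.jaro:.6g}")
    click.echo(f"PWC_auto: {rec.pwc_auto:.6g}")


@cli.command()
@click.argument("input_path", type=click.Path(exists=True, dir_okay=False))
@click.argument("output_path", type=click.Path(dir_okay=False))
@click.option("--metrics", default="tsr", show_default=True,
              help="Comma-separated subset of tsr,levenshtein,jaro,pwc.")
@_add_options(_common)
@click.option("-v", "--verbose", is_flag=True, help="Row-level diagnostics.")
def score(input_path, output_path, metrics, whitespace_mode, round_,
          keep_punctuation, no_lowercase, verbose):
    """Score a CSV with `target` and `response` columns."""
    cfg = _config_from_flags(
        tuple(m.strip() for m in metrics.split(",") if m.strip()),
        whitespace_mode, round_, keep_punctuation, no_lowercase,
    )
    try:
        summary = score_file(input_path, output_path, cfg)
    except BatchScoreError as err:
        click.echo(f"error: {err}", err=True)
        sys.exit(1)
    click.echo(
        f"scored {summary.rows_scored}/{summary.rows_read} rows "
        f"({summary.empty_responses} empty responses) -> {output_path}",
        err=True,
    )
    if verbose:
        click.echo(f"config: {cfg}", err=True)


@cli.command()
@click.argument("output_path", type=click.Path(dir_okay=False))
@click.option("--n", default=1000, show_default=True, help="Records to generate.")
@click.option("--seed", default=0, show_default=True)
@click.option("--report-prob", default=0.7, show_default=True)
@click.option("--typo-rate", default=0.05, show_default=True)
@click.option("--shuffle-prob", default=0.1, show_default=True)
@click.option("--intrusion-rate", default=0.1, show_default=True)
@click.option("--min-words", default=5, show_default=True)
@click.option("--max-words", default=20, show_default=True)
def simulate(output_path, n, seed, report_prob, typo_rate, shuffle_prob,
             intrusion_rate, min_words, max_words):
    """Write a synthetic corpus CSV with known ground truth."""
    model = synthcorpus.ErrorModel(
        report_prob=report_prob, typo_rate=typo_rate,
        shuffle_prob=shuffle_prob, intrusion_rate=intrusion_rate, seed=seed,
    )
    records = synthcorpus.generate_corpus(
        n, model, length_range=(min_words, max_words)
    )
    with open(output_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["target", "response", "true_report_fraction", "n_typos"])
        for rec in records:
            writer.writerow(
                [rec.target, rec.response,
                 format(rec.true_report_fraction, ".6g"), rec.n_typos]
            )
    click.echo(f"wrote {n} simulated records -> {output_path}", err=True)


@cli.command()
@click.argument("input_path", type=click.Path(exists=True, dir_okay=False))
@click.argument("output_path", type=click.Path(dir_okay=False))
@click.option("--reference", default="true_report_fraction", show_default=True,
              help="Reference column to correlate the metrics against.")
def evaluate(input_path, output_path, reference):
    """Correlate metric columns of a scored CSV against a reference column."""
    import pandas as pd

    scored = pd.read_csv(input_path)
    if not any(c in scored.columns for c in ("TSR_score", "LS_score")):
        # bare simulate output: score it in memory first
        @dataclass
        class _Rec:
            target: str
            response: str
            true_report_fraction: float

        records = [
            _Rec(str(t), "" if r != r else str(r), float(f))
            for t, r, f in zip(
                scored["target"], scored["response"], scored[reference]
            )
        ]
        scored = score_corpus(records)
    try:
        table = evaluate_metrics(scored, reference)
    except ValueError as err:
        click.echo(f"error: {err}", err=True)
        sys.exit(1)
    table.to_csv(output_path, index=False)
    click.echo(table.to_string(index=False), err=True)


if __name__ == "__main__":
    cli()
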