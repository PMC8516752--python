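"""Seeded simulator of listener transcripts with known ground truth.

The published validation datasets for transcript-scoring metrics are
human-scored listening experiments that are not redistributable, so this
module generates synthetic target sentences and simulated listener responses
whose true proportion of reported target words is known by construction.
The error processes emulate what degrades real transcripts:

* **omission** — under noise a listener misses words; each target word is
  reported independently with probability ``report_prob``;
* **typos** — typed responses carry adjacent-key substitutions (e.g. 'wayer'
  for 'water', [Y] hit instead of [T]); each character of a reported word is
  replaced by a keyboard neighbour with probability ``typo_rate``;
* **word-order changes** — with probability ``shuffle_prob`` the reported
  words are permuted;
* **intrusions** — guessed words not in the target are inserted, their count
  drawn Poisson with mean ``intrusion_rate``.

Everything is driven by numpy generators spawned per record from a master
seed, so individual records are independently reproducible.  The simulation
is synthetic plumbing for evaluating the metrics, not a psycholinguistic
model: confusions are orthographic only and the word frequencies are flat.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ErrorModel",
    "CorpusRecord",
    "QWERTY_ADJACENT",
    "DEFAULT_LEXICON",
    "generate_targets",
    "corrupt_response",
    "generate_corpus",
]


def _qwerty_neighbours() -> dict[str, tuple[str, ...]]:
    rows = ["qwertyuiop", "asdfghjkl", "zxcvbnm"]
    adj: dict[str, set[str]] = {}
    for r, row in enumerate(rows):
        for i, ch in enumerate(row):
            nbrs = adj.setdefault(ch, set())
            if i > 0:
                nbrs.add(row[i - 1])
            if i + 1 < len(row):
                nbrs.add(row[i + 1])
            # staggered rows: key (r, i) sits between (r+1, i-1) and (r+1, i)
            if r + 1 < len(rows):
                below = rows[r + 1]
                for k in (i - 1, i):
                    if 0 <= k < len(below):
                        nbrs.add(below[k])
            if r > 0:
                above = rows[r - 1]
                for k in (i, i + 1):
                    if 0 <= k < len(above):
                        nbrs.add(above[k])
    return {ch: tuple(sorted(n)) for ch, n in adj.items()}


#: Horizontal + vertical neighbours on a QWERTY layout, e.g. t -> (f, g, r, y).
QWERTY_ADJACENT: dict[str, tuple[str, ...]] = _qwerty_neighbours()

#: Packaged neutral word list (~200 common English words) used for target
#: sentences and intrusions; no external download.
DEFAULT_LEXICON: tuple[str, ...] = (
    "about", "after", "again", "air", "all", "along", "also", "always",
    "animal", "another", "answer", "any", "apple", "around", "ask", "away",
    "back", "ball", "bank", "basket", "bear", "because", "before", "begin",
    "below", "between", "big", "bird", "black", "blue", "boat", "book",
    "both", "box", "boy", "bread", "bring", "brother", "brown", "build",
    "call", "car", "carry", "chair", "change", "child", "city", "clean",
    "close", "cloud", "cold", "come", "could", "country", "cut", "dark",
    "day", "deep", "dinner", "doctor", "dog", "door", "down", "draw",
    "dream", "drink", "drive", "early", "earth", "eat", "end", "even",
    "evening", "every", "eye", "face", "fall", "family", "far", "farm",
    "fast", "father", "feel", "field", "find", "fire", "first", "fish",
    "floor", "flower", "follow", "food", "foot", "forest", "form", "friend",
    "from", "front", "garden", "girl", "give", "glass", "good", "grass",
    "great", "green", "ground", "grow", "hand", "happy", "hard", "have",
    "head", "hear", "help", "here", "high", "hill", "hold", "home", "horse",
    "house", "keep", "kind", "king", "kitchen", "know", "lake", "land",
    "large", "last", "late", "laugh", "learn", "leave", "letter", "light",
    "like", "line", "listen", "little", "live", "long", "look", "love",
    "make", "many", "mind", "money", "moon", "morning", "mother", "mountain",
    "move", "music", "name", "near", "never", "next", "night", "north",
    "number", "open", "over", "paper", "part", "people", "picture", "place",
    "plant", "play", "point", "put", "rain", "read", "red", "right", "river",
    "road", "rock", "room", "round", "run", "said", "school", "sea", "seem",
    "sell", "ship", "short", "should", "show", "side", "sing", "sister",
    "sleep", "small", "snow", "some", "song", "soon", "sound", "south",
    "stand", "star", "start", "stay", "still", "stone", "stop", "story",
    "street", "strong", "summer", "table", "take", "talk", "tell", "than",
    "that", "them", "then", "there", "thing", "think", "this", "three",
    "time", "today", "together", "town", "tree", "turn", "under", "until",
    "walk", "warm", "watch", "water", "where", "white", "wind", "window",
    "winter", "with", "word", "work", "world", "write", "year", "yellow",
    "young",
)


@dataclass(frozen=True)
class ErrorModel:
    """Parameters of the transcription-error simulation.

    All probabilities are per-event and lie in [0, 1]; ``intrusion_rate`` is
    the expected count of extraneous words per response.  ``keyboard_map``
    maps a character to its substitutable neighbours; characters absent from
    the map are never mistyped.
    """

    report_prob: float = 0.7
    typo_rate: float = 0.05
    shuffle_prob: float = 0.1
    intrusion_rate: float = 0.1
    keyboard_map: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(QWERTY_ADJACENT)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("report_prob", "typo_rate", "shuffle_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.intrusion_rate < 0:
            raise ValueError(f"intrusion_rate must be >= 0, got {self.intrusion_rate}")


@dataclass(frozen=True)
class CorpusRecord:
    """One simulated trial: target, response, and its ground truth.

    ``true_report_fraction`` is the number of target words the simulated
    listener reported divided by the number of target words — the quantity a
    percentage-words-correct score estimates.  Typos and intrusions do not
    change it.
    """

    target: str
    response: str
    true_report_fraction: float
    n_typos: int


def generate_targets(
    n: int,
    length_range: tuple[int, int] = (5, 20),
    lexicon: tuple[str, ...] = DEFAULT_LEXICON,
    seed: int = 0,
) -> list[str]:
    """Generate ``n`` target sentences of ``length_range`` words from ``lexicon``.

    Deterministic given the seed.  Sentence lengths emulate typical
    intelligibility-test materials (5-20 word sentences by default).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = length_range
    if not 1 <= lo <= hi:
        raise ValueError(f"invalid length_range {length_range}")
    if not lexicon:
        raise ValueError("lexicon must be non-empty")
    rng = np.random.default_rng(seed)
    words = np.asarray(lexicon, dtype=object)
    out = []
    for _ in range(n):
        k = int(rng.integers(lo, hi + 1))
        out.append(" ".join(rng.choice(words, size=k)))
    return out


def _mistype(word: str, model: ErrorModel, rng: np.random.Generator) -> tuple[str, int]:
    chars = list(word)
    hits = 0
    for i, ch in enumerate(chars):
        nbrs = model.keyboard_map.get(ch)
        if nbrs and rng.random() < model.typo_rate:
            chars[i] = nbrs[int(rng.integers(len(nbrs)))]
            hits += 1
    return "".join(chars), hits


def corrupt_response(
    target: str,
    model: ErrorModel,
    rng: np.random.Generator,
    lexicon: tuple[str, ...] = DEFAULT_LEXICON,
) -> CorpusRecord:
    """Simulate one listener response to ``target`` under ``model``.

    Each target word is kept with ``report_prob``; kept words receive
    adjacent-key substitutions; with ``shuffle_prob`` the kept words are
    permuted; intrusions sampled from ``lexicon`` excluding the target's own
    words are inserted at random positions.
    """
    words = target.split()
    if not words:
        raise ValueError("target must be non-empty")
    keep = rng.random(len(words)) < model.report_prob
    kept = [w for w, k in zip(words, keep) if k]
    frac = len(kept) / len(words)

    n_typos = 0
    typed = []
    for w in kept:
        tw, hits = _mistype(w, model, rng)
        typed.append(tw)
        n_typos += hits

    if len(typed) > 1 and rng.random() < model.shuffle_prob:
        typed = [typed[i] for i in rng.permutation(len(typed))]

    n_intr = int(rng.poisson(model.intrusion_rate))
    if n_intr:
        pool = [w for w in lexicon if w not in set(words)]
        for _ in range(min(n_intr, len(pool)) if pool else 0):
            w = pool[int(rng.integers(len(pool)))]
            pos = int(rng.integers(len(typed) + 1))
            typed.insert(pos, w)

    return CorpusRecord(target, " ".join(typed), frac, n_typos)


def generate_corpus(
    n: int,
    model: ErrorModel = ErrorModel(),
    length_range: tuple[int, int] = (5, 20),
    lexicon: tuple[str, ...] = DEFAULT_LEXICON,
    report_prob_range: tuple[float, float] | None = None,
    seed: int | None = None,
) -> list[CorpusRecord]:
    """Generate ``n`` target/response pairs under ``model``.

    With ``report_prob_range`` set, each record draws its own report
    probability uniformly from that interval (emulating trials at varying
    intelligibility levels); otherwise ``model.report_prob`` applies to all.
    The random stream is split per record from the master seed (``seed``
    overrides ``model.seed`` when given) so records are independently
    reproducible.
    """
    master = model.seed if seed is None else seed
    targets = generate_targets(n, length_range, lexicon, seed=master)
    streams = np.random.SeedSequence(master).spawn(n + 1)
    prob_rng = np.random.default_rng(streams[0])
    out = []
    for i, tgt in enumerate(targets):
        m = model
        if report_prob_range is not None:
            lo, hi = report_prob_range
            m = replace(model, report_prob=float(prob_rng.uniform(lo, hi)))
        rec_rng = np.random.default_rng(streams[i + 1])
        out.append(corrupt_response(tgt, m, rec_rng, lexicon))
    return out
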