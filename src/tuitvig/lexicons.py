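"""Negation, emotion and dual polarity scoring by lexicon lookup.

Three scorer families operate on tokenized tweets:

* negation counting against a closed Spanish negation-cue list;
* six-emotion counting (happiness, sadness, anger, fear, disgust,
  surprise), where a multi-emotion term increments every listed emotion;
* polarity labelling under two schemes — *binary* (signed word list,
  tweet label by hit majority) and *graded* (real-valued word list in
  [-1, 1], tweet label by mean matched value against a moderate/strong
  threshold ``t_mod``).

All scorers are deterministic, order-independent within a tweet, and
additive over corpus concatenation.  The bundled lexicons are synthetic
stand-ins (see :mod:`tuitvig._vocabulary`); loaders accept externally
supplied TSV resources with the same layout.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import _vocabulary as vocab
from .corpus_io import Corpus
from .tokenizer import Token, tokenize_tweet, words

EMOTIONS = ("happiness", "sadness", "anger", "fear", "disgust", "surprise")

BINARY_LABELS = ("positive", "negative")
GRADED_LABELS = ("positive", "moderate_positive", "moderate_negative", "negative")
NO_POLARITY = "none"

DEFAULT_T_MOD = 0.5


# ---------------------------------------------------------------------------
# Lexicon containers & loaders


@dataclass(frozen=True)
class NegationLexicon:
    terms: frozenset[str]

    @classmethod
    def bundled(cls) -> "NegationLexicon":
        return cls(frozenset(vocab.NEGATIONS))

    @classmethod
    def from_file(cls, path: str | Path) -> "NegationLexicon":
        terms = {
            line.strip().lower()
            for line in Path(path).read_text(encoding="utf-8").splitlines()
            if line.strip()
        }
        return cls(frozenset(terms))


@dataclass(frozen=True)
class EmotionLexicon:
    entries: Mapping[str, tuple[str, ...]]  # term -> emotions

    def __post_init__(self) -> None:
        for term, emos in self.entries.items():
            if term != term.lower():
                raise ValueError(f"emotion term not lower-case: {term!r}")
            bad = set(emos) - set(EMOTIONS)
            if bad:
                raise ValueError(f"unknown emotions {bad} for {term!r}")

    @classmethod
    def bundled(cls) -> "EmotionLexicon":
        entries: dict[str, tuple[str, ...]] = {}
        for term, emo in vocab.emotion_lexicon_rows():
            entries[term] = entries.get(term, ()) + (emo,)
        return cls(entries)

    @classmethod
    def from_file(cls, path: str | Path) -> "EmotionLexicon":
        entries: dict[str, tuple[str, ...]] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            term, emo = line.rstrip("\n").split("\t")[:2]
            entries[term.lower()] = entries.get(term.lower(), ()) + (emo,)
        return cls(entries)


@dataclass(frozen=True)
class PolarityLexicon:
    """term -> signed value; binary lexicons use ±1, graded use [-1, 1]."""

    entries: Mapping[str, float]
    scheme: str = "binary"

    def __post_init__(self) -> None:
        if self.scheme not in ("binary", "graded"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        for term, v in self.entries.items():
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"value {v} out of [-1,1] for {term!r}")

    @classmethod
    def bundled_binary(cls) -> "PolarityLexicon":
        return cls(dict(vocab.binary_lexicon_rows()), "binary")

    @classmethod
    def bundled_graded(cls) -> "PolarityLexicon":
        return cls(dict(vocab.graded_lexicon_rows()), "graded")

    @classmethod
    def from_file(cls, path: str | Path, scheme: str = "binary") -> "PolarityLexicon":
        entries: dict[str, float] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            term, value = line.rstrip("\n").split("\t")[:2]
            entries[term.lower()] = float(value)
        return cls(entries, scheme)

    def inverted(self) -> "PolarityLexicon":
        return PolarityLexicon({t: -v for t, v in self.entries.items()}, self.scheme)


# ---------------------------------------------------------------------------
# Tweet-level scorers


def detect_negations(tokens: Iterable[Token], lexicon: NegationLexicon | None = None) -> int:
    """Number of word tokens that are negation cues (count, not scope)."""
    lexicon = lexicon or NegationLexicon.bundled()
    return sum(1 for w in words(tokens) if w in lexicon.terms)


def score_emotions(
    tokens: Iterable[Token], lexicon: EmotionLexicon | None = None
) -> dict[str, int]:
    lexicon = lexicon or EmotionLexicon.bundled()
    counts = {e: 0 for e in EMOTIONS}
    for w in words(tokens):
        for emo in lexicon.entries.get(w, ()):
            counts[emo] += 1
    return counts


def score_polarity_binary(
    tokens: Iterable[Token],
    lexicon: PolarityLexicon | None = None,
    tie_rule: str = NO_POLARITY,
) -> str:
    """Hit-majority label: more positive hits -> positive, etc.

    No hits -> ``none``; an exact tie defaults to ``none`` (configurable to
    ``positive`` or ``negative``).
    """
    lexicon = lexicon or PolarityLexicon.bundled_binary()
    pos = neg = 0
    for w in words(tokens):
        v = lexicon.entries.get(w)
        if v is None:
            continue
        if v > 0:
            pos += 1
        elif v < 0:
            neg += 1
    if pos == neg == 0:
        return NO_POLARITY
    if pos > neg:
        return "positive"
    if neg > pos:
        return "negative"
    return tie_rule


def score_polarity_graded(
    tokens: Iterable[Token],
    lexicon: PolarityLexicon | None = None,
    t_mod: float = DEFAULT_T_MOD,
) -> str:
    """Mean-matched-value label with a moderate band below ``t_mod``."""
    if not 0 < t_mod < 1:
        raise ValueError("t_mod must be in (0, 1)")
    lexicon = lexicon or PolarityLexicon.bundled_graded()
    values = [lexicon.entries[w] for w in words(tokens) if w in lexicon.entries]
    if not values:
        return NO_POLARITY
    s = sum(values) / len(values)
    if s == 0:
        return NO_POLARITY
    if s >= t_mod:
        return "positive"
    if s > 0:
        return "moderate_positive"
    if s <= -t_mod:
        return "negative"
    return "moderate_negative"


# ---------------------------------------------------------------------------
# Corpus-level aggregates


def corpus_negation_counts(
    corpus: Corpus, lexicon: NegationLexicon | None = None
) -> list[int]:
    """Per-tweet negation-cue counts, corpus order preserved."""
    lexicon = lexicon or NegationLexicon.bundled()
    return [detect_negations(tokenize_tweet(t.text), lexicon) for t in corpus.tweets]


def corpus_emotion_counts(
    corpus: Corpus, lexicon: EmotionLexicon | None = None
) -> dict[str, int]:
    lexicon = lexicon or EmotionLexicon.bundled()
    total = Counter({e: 0 for e in EMOTIONS})
    for t in corpus.tweets:
        total.update(score_emotions(tokenize_tweet(t.text), lexicon))
    return {e: total[e] for e in EMOTIONS}


def corpus_polarity_labels(
    corpus: Corpus,
    scheme: str = "binary",
    lexicon: PolarityLexicon | None = None,
    t_mod: float = DEFAULT_T_MOD,
    tie_rule: str = NO_POLARITY,
) -> list[str]:
    out = []
    for t in corpus.tweets:
        toks = tokenize_tweet(t.text)
        if scheme == "binary":
            out.append(score_polarity_binary(toks, lexicon, tie_rule))
        elif scheme == "graded":
            out.append(score_polarity_graded(toks, lexicon, t_mod))
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
    return out


def polarity_prevalence(labels: Sequence[str]) -> tuple[float, dict[str, float]]:
    """(fraction of tweets with polarity, conditional label shares).

    The share dictionary is empty when no tweet carries polarity.
    """
    n = len(labels)
    with_pol = [lab for lab in labels if lab != NO_POLARITY]
    if n == 0 or not with_pol:
        return 0.0, {}
    counts = Counter(with_pol)
    k = len(with_pol)
    return k / n, {lab: c / k for lab, c in sorted(counts.items())}


__all__ = [
    "EMOTIONS",
    "BINARY_LABELS",
    "GRADED_LABELS",
    "NO_POLARITY",
    "DEFAULT_T_MOD",
    "NegationLexicon",
    "EmotionLexicon",
    "PolarityLexicon",
    "detect_negations",
    "score_emotions",
    "score_polarity_binary",
    "score_polarity_graded",
    "corpus_negation_counts",
    "corpus_emotion_counts",
    "corpus_polarity_labels",
    "polarity_prevalence",
]
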