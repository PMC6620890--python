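"""Part-of-speech profiling and pronoun person/number classification.

Tagging goes through a minimal contract — any callable mapping a word to a
``(pos, person)`` pair can serve — with a bundled dictionary tagger that
looks surface forms up in a tagged-vocabulary TSV.  The dictionary route is
deterministic, which keeps recovery tests exact; a statistical tagger can be
plugged in for real corpora without touching the profiling code.

Eight grammatical categories are profiled (noun, verb, pronoun, adjective,
determiner, adverb, adposition, conjunction); anything else — unknown words,
interjections, non-word tokens — is ``other`` and excluded from the
eight-way totals that percentages are computed over.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol

from . import _vocabulary as vocab
from .corpus_io import Corpus
from .tokenizer import Token, tokenize_tweet

log = logging.getLogger("tuitvig")

POS_CATEGORIES = (
    "noun", "verb", "pronoun", "adjective",
    "determiner", "adverb", "adposition", "conjunction",
)
OTHER = "other"
PRONOUN_PERSONS = ("1S", "1P", "2S", "2P", "3S", "3P")


class Tagger(Protocol):
    def __call__(self, word: str) -> tuple[str, str | None]:
        """Return (pos category, pronoun person-or-None) for a word form."""


@dataclass(frozen=True)
class TaggedToken:
    token: Token
    pos: str
    pronoun_person: str | None = None

    def __post_init__(self) -> None:
        if self.pos not in POS_CATEGORIES + (OTHER,):
            raise ValueError(f"unknown POS {self.pos!r}")
        if self.pronoun_person is not None and self.pos != "pronoun":
            raise ValueError("person set on a non-pronoun token")


class DictionaryTagger:
    """Exact surface-form lookup in a word -> (pos, person) table."""

    def __init__(self, table: dict[str, tuple[str, str | None]]):
        self.table = table

    def __call__(self, word: str) -> tuple[str, str | None]:
        return self.table.get(word.lower(), (OTHER, None))

    @classmethod
    def bundled(cls) -> "DictionaryTagger":
        table: dict[str, tuple[str, str | None]] = {}
        person = vocab.pronoun_person_table()
        for pos, inventory in vocab.pos_inventories().items():
            for word in inventory:
                table[word] = (pos, person.get(word))
        return cls(table)

    @classmethod
    def from_file(cls, path: str | Path) -> "DictionaryTagger":
        """Load a TSV of ``word<TAB>pos[<TAB>person]`` rows."""
        table: dict[str, tuple[str, str | None]] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            word, pos = parts[0], parts[1]
            person = parts[2] if len(parts) > 2 and parts[2] else None
            table[word.lower()] = (pos, person)
        return cls(table)


def tag_tokens(tokens: Iterable[Token], tagger: Tagger) -> list[TaggedToken]:
    """Tag word tokens; all non-word tokens get ``other``."""
    out: list[TaggedToken] = []
    for tok in tokens:
        if tok.kind != "word":
            out.append(TaggedToken(tok, OTHER))
            continue
        try:
            pos, person = tagger(tok.normalized)
        except Exception as exc:  # tagger failure is data, not fatal
            log.warning("tagger failed on %r: %s", tok.surface, exc)
            pos, person = OTHER, None
        if pos not in POS_CATEGORIES:
            pos, person = OTHER, None
        out.append(TaggedToken(tok, pos, person if pos == "pronoun" else None))
    return out


@dataclass
class POSProfile:
    counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in POS_CATEGORIES}
    )

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def percentages(self) -> dict[str, float]:
        tot = self.total
        if tot == 0:
            return {c: 0.0 for c in POS_CATEGORIES}
        return {c: 100.0 * self.counts[c] / tot for c in POS_CATEGORIES}

    def __add__(self, other: "POSProfile") -> "POSProfile":
        return POSProfile({c: self.counts[c] + other.counts[c] for c in POS_CATEGORIES})


@dataclass
class PronounProfile:
    counts: dict[str, int] = field(
        default_factory=lambda: {p: 0 for p in PRONOUN_PERSONS}
    )

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def percentages(self) -> dict[str, float]:
        tot = self.total
        if tot == 0:
            return {p: 0.0 for p in PRONOUN_PERSONS}
        return {p: 100.0 * self.counts[p] / tot for p in PRONOUN_PERSONS}

    def __add__(self, other: "PronounProfile") -> "PronounProfile":
        return PronounProfile(
            {p: self.counts[p] + other.counts[p] for p in PRONOUN_PERSONS}
        )


def pos_profile(corpus: Corpus, tagger: Tagger | None = None) -> POSProfile:
    """Aggregate POS counts over all word tokens of a corpus."""
    tagger = tagger or DictionaryTagger.bundled()
    prof = POSProfile()
    for tweet in corpus.tweets:
        for tt in tag_tokens(tokenize_tweet(tweet.text), tagger):
            if tt.pos in prof.counts:
                prof.counts[tt.pos] += 1
    return prof


def pronoun_profile(corpus: Corpus, tagger: Tagger | None = None) -> PronounProfile:
    """Aggregate personal-pronoun person/number counts over a corpus."""
    tagger = tagger or DictionaryTagger.bundled()
    prof = PronounProfile()
    for tweet in corpus.tweets:
        for tt in tag_tokens(tokenize_tweet(tweet.text), tagger):
            if tt.pronoun_person in prof.counts:
                prof.counts[tt.pronoun_person] += 1
    return prof


__all__ = [
    "POS_CATEGORIES",
    "PRONOUN_PERSONS",
    "OTHER",
    "Tagger",
    "TaggedToken",
    "DictionaryTagger",
    "tag_tokens",
    "POSProfile",
    "PronounProfile",
    "pos_profile",
    "pronoun_profile",
]
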