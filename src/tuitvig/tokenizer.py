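"""Twitter-aware tokenization and surface-feature counting.

The tokenizer is rule-based and total: every non-whitespace character of the
input ends up in exactly one token, so concatenating token surfaces (ignoring
whitespace) reconstructs the tweet.  Token kinds partition the stream into
{word, mention, hashtag, url, emoji, punctuation, number}.

Emoji are recognised by explicit Unicode Emoji property ranges; zero-width-
joiner sequences (family / profession emoji), variation selectors, skin-tone
modifiers and regional-indicator flag pairs are merged into single tokens.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

TOKEN_KINDS = ("word", "mention", "hashtag", "url", "emoji", "punctuation", "number")

# Emoji-presentation base characters (conservative BMP/SMP ranges).
_EMOJI_BASE = (
    "\U0001F300-\U0001F5FF"  # symbols & pictographs
    "\U0001F600-\U0001F64F"  # emoticons
    "\U0001F680-\U0001F6FF"  # transport
    "\U0001F900-\U0001F9FF"  # supplemental symbols
    "\U0001FA70-\U0001FAFF"
    "☀-➿"          # misc symbols & dingbats (☀ ❤ ✊ …)
    "⬀-⯿"
    "←-⇿"
    "©®‼⁉™ℹ"
)
_FLAG = "[\U0001F1E6-\U0001F1FF]{2}"
_MOD = "[\U0001F3FB-\U0001F3FF]"      # skin tones
_VS = "\uFE0F"                        # emoji variation selector
_ZWJ = "\u200D"

_EMOJI_UNIT = f"(?:{_FLAG}|[{_EMOJI_BASE}]{_MOD}?{_VS}?)"
_EMOJI_SEQ = f"{_EMOJI_UNIT}(?:{_ZWJ}{_EMOJI_UNIT})*"

_TOKEN_RE = re.compile(
    rf"""
    (?P<url>https?://\S+|(?:www\.|t\.co/)\S+)
  | (?P<mention>@\w+)
  | (?P<hashtag>\#\w+)
  | (?P<emoji>{_EMOJI_SEQ})
  | (?P<word>[^\W\d_]+)
  | (?P<number>\d+(?:[.,]\d+)*)
  | (?P<punctuation>\S)
    """,
    re.VERBOSE | re.UNICODE,
)


@dataclass(frozen=True)
class Token:
    surface: str
    kind: str

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("empty token surface")
        if self.kind not in TOKEN_KINDS:
            raise ValueError(f"unknown token kind {self.kind!r}")

    @property
    def normalized(self) -> str:
        return self.surface.lower()


@dataclass(frozen=True)
class EntityCounts:
    hashtags: int = 0
    links: int = 0
    mentions: int = 0
    emojis: int = 0


def tokenize_tweet(text: str) -> list[Token]:
    """Split a tweet into typed tokens; deterministic and whitespace-lossless."""
    tokens: list[Token] = []
    for m in _TOKEN_RE.finditer(text):
        kind = m.lastgroup
        assert kind is not None
        tokens.append(Token(m.group(), kind))
    return tokens


def words(tokens: Iterable[Token]) -> list[str]:
    """Lower-cased surfaces of the word-kind tokens."""
    return [t.normalized for t in tokens if t.kind == "word"]


def count_entities(tokens: Iterable[Token]) -> EntityCounts:
    c = Counter(t.kind for t in tokens)
    return EntityCounts(
        hashtags=c["hashtag"], links=c["url"], mentions=c["mention"], emojis=c["emoji"]
    )


def char_count(text: str) -> int:
    """Unicode code points of the raw text, URLs and mentions included.

    Use ``exclude_entities=True`` on :func:`char_count_ex` for the variant
    that drops them.
    """
    return len(text)


def char_count_ex(text: str, exclude_entities: bool = False) -> int:
    if not exclude_entities:
        return len(text)
    kept = [t.surface for t in tokenize_tweet(text) if t.kind not in ("url", "mention")]
    return len("".join(kept))


def top_words(
    texts: Iterable[str], k: int = 200, stopwords: Sequence[str] | set[str] = ()
) -> list[tuple[str, int]]:
    """The ``k`` most frequent word tokens, stopwords removed.

    Ties are broken lexicographically so rankings are reproducible.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    stop = {s.lower() for s in stopwords}
    counts: Counter[str] = Counter()
    for text in texts:
        counts.update(w for w in words(tokenize_tweet(text)) if w not in stop)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


__all__ = [
    "Token",
    "EntityCounts",
    "TOKEN_KINDS",
    "tokenize_tweet",
    "words",
    "count_entities",
    "char_count",
    "char_count_ex",
    "top_words",
]
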