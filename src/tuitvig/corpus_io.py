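"""Reading, validation and filtering of tweet corpora stored as JSON-lines.

A corpus is a flat file with one JSON object per tweet.  Field names follow
the Twitter REST API v1.1 payload by default (``id_str``, ``user.id_str``,
``full_text``/``text``, ``created_at``, ``user.utc_offset``,
``user.description``, ``retweeted_status`` presence, ``lang``) but any layout
can be mapped onto the internal :class:`Tweet` record through a schema
dictionary, so corpora exported by other collectors remain readable.

Timestamps are normalised to UTC at parse time; all local-time arithmetic is
deferred to :mod:`tuitvig.temporal`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

log = logging.getLogger("tuitvig")

#: Largest UTC offset Twitter ever reports (UTC+14 / UTC-14), in seconds.
MAX_UTC_OFFSET = 50_400

#: Default mapping from internal field names to JSONL keys (dotted = nested).
DEFAULT_SCHEMA: Mapping[str, str] = {
    "tweet_id": "id_str",
    "user_id": "user.id_str",
    "text": "full_text",
    "text_fallback": "text",
    "created_at": "created_at",
    "utc_offset": "user.utc_offset",
    "is_retweet": "is_retweet",
    "lang": "lang",
    "description": "user.description",
}

#: Accepted timestamp layouts: Twitter's native format plus ISO 8601.
_TIME_FORMATS = ("%a %b %d %H:%M:%S %z %Y",)

RETWEET_MARKER = "RT @"

DATASET_LABELS = ("control", "depressive_users", "depressive_tweets")


@dataclass(frozen=True)
class Tweet:
    """One message: text plus the metadata the analyses need."""

    tweet_id: str
    user_id: str
    text: str
    created_at_utc: datetime
    utc_offset_seconds: int | None = None
    is_retweet: bool = False
    lang: str = "es"

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValueError(f"tweet {self.tweet_id}: empty text")
        if self.created_at_utc.tzinfo is None:
            object.__setattr__(
                self, "created_at_utc", self.created_at_utc.replace(tzinfo=timezone.utc)
            )
        off = self.utc_offset_seconds
        if off is not None and not -MAX_UTC_OFFSET <= off <= MAX_UTC_OFFSET:
            raise ValueError(f"tweet {self.tweet_id}: utc offset {off} out of range")


@dataclass(frozen=True)
class UserProfile:
    """A user id and the free-text profile description (may be empty)."""

    user_id: str
    description: str = ""


@dataclass
class Corpus:
    """An ordered tweet collection with resolvable user profiles.

    ``label`` names which of the three study datasets this corpus plays the
    role of; it is fixed at construction.
    """

    label: str
    tweets: list[Tweet] = field(default_factory=list)
    profiles: dict[str, UserProfile] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in DATASET_LABELS:
            raise ValueError(f"unknown corpus label {self.label!r}")
        missing = {t.user_id for t in self.tweets} - set(self.profiles)
        # Auto-create empty profiles rather than fail: collectors routinely
        # store profile text separately from the tweet stream.
        for uid in missing:
            self.profiles[uid] = UserProfile(uid)

    def __len__(self) -> int:
        return len(self.tweets)

    def with_tweets(self, tweets: Iterable[Tweet]) -> "Corpus":
        return Corpus(self.label, list(tweets), dict(self.profiles))

    def user_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.tweets:
            seen.setdefault(t.user_id, None)
        return list(seen)

    def timelines(self) -> dict[str, list[Tweet]]:
        """Per-user tweet lists, preserving corpus order within users."""
        out: dict[str, list[Tweet]] = {}
        for t in self.tweets:
            out.setdefault(t.user_id, []).append(t)
        return out


# ---------------------------------------------------------------------------
# JSONL parsing


def _dig(obj: Mapping, dotted: str):
    cur = obj
    for part in dotted.split("."):
        if not isinstance(cur, Mapping) or part not in cur:
            return None
        cur = cur[part]
    return cur


def parse_timestamp(value) -> datetime:
    """Parse Twitter-native or ISO 8601 timestamps; naive times are UTC."""
    if isinstance(value, (int, float)):
        return datetime.fromtimestamp(value, tz=timezone.utc)
    s = str(value)
    for fmt in _TIME_FORMATS:
        try:
            return datetime.strptime(s, fmt).astimezone(timezone.utc)
        except ValueError:
            pass
    dt = datetime.fromisoformat(s)
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.astimezone(timezone.utc)


def _tweet_from_obj(obj: Mapping, schema: Mapping[str, str]) -> tuple[Tweet, str]:
    text = _dig(obj, schema["text"])
    if text is None and "text_fallback" in schema:
        text = _dig(obj, schema["text_fallback"])
    raw_rt = _dig(obj, schema.get("is_retweet", "is_retweet"))
    if raw_rt is None:
        # v1.1 marks retweets by the presence of a nested retweeted_status
        raw_rt = _dig(obj, "retweeted_status") is not None
    offset = _dig(obj, schema.get("utc_offset", "utc_offset"))
    tweet = Tweet(
        tweet_id=str(_dig(obj, schema["tweet_id"])),
        user_id=str(_dig(obj, schema["user_id"])),
        text=str(text),
        created_at_utc=parse_timestamp(_dig(obj, schema["created_at"])),
        utc_offset_seconds=None if offset is None else int(offset),
        is_retweet=bool(raw_rt),
        lang=str(_dig(obj, schema.get("lang", "lang")) or "und"),
    )
    desc = _dig(obj, schema.get("description", "user.description")) or ""
    return tweet, str(desc)


def read_corpus(
    path: str | Path,
    label: str = "control",
    schema: Mapping[str, str] | None = None,
    deduplicate: bool = True,
) -> Corpus:
    """Read a JSONL corpus, skipping (and counting) malformed lines.

    Raises ``ValueError`` when more than half of the non-empty lines fail to
    parse — that signals a wrong schema rather than line-level corruption.
    Duplicate tweet ids (possible when collections overlap) are dropped,
    keeping the first occurrence.
    """
    schema = dict(DEFAULT_SCHEMA, **(schema or {}))
    path = Path(path)
    tweets: list[Tweet] = []
    profiles: dict[str, UserProfile] = {}
    seen_ids: set[str] = set()
    n_bad = n_lines = n_dup = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            n_lines += 1
            try:
                obj = json.loads(line)
                tweet, desc = _tweet_from_obj(obj, schema)
            except (ValueError, TypeError, KeyError) as exc:
                n_bad += 1
                log.warning("%s:%d skipped malformed line (%s)", path.name, lineno, exc)
                continue
            if deduplicate and tweet.tweet_id in seen_ids:
                n_dup += 1
                continue
            seen_ids.add(tweet.tweet_id)
            tweets.append(tweet)
            if tweet.user_id not in profiles or (desc and not profiles[tweet.user_id].description):
                profiles[tweet.user_id] = UserProfile(tweet.user_id, desc)
    if n_lines == 0:
        log.warning("%s: empty corpus file", path.name)
    elif n_bad * 2 > n_lines:
        raise ValueError(f"{path}: {n_bad}/{n_lines} malformed lines; wrong schema?")
    if n_dup:
        log.info("%s: dropped %d duplicate tweet ids", path.name, n_dup)
    corpus = Corpus(label, tweets, profiles)
    corpus.skipped_lines = n_bad  # type: ignore[attr-defined]
    return corpus


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as JSONL using the default v1.1-style field layout."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for t in corpus.tweets:
            prof = corpus.profiles.get(t.user_id)
            obj = {
                "id_str": t.tweet_id,
                "user": {
                    "id_str": t.user_id,
                    "utc_offset": t.utc_offset_seconds,
                    "description": prof.description if prof else "",
                },
                "full_text": t.text,
                "created_at": t.created_at_utc.strftime("%a %b %d %H:%M:%S %z %Y"),
                "is_retweet": t.is_retweet,
                "lang": t.lang,
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# Filters


def is_retweet(tweet: Tweet) -> bool:
    """Metadata flag OR a leading ``RT @`` text marker (conservative)."""
    return tweet.is_retweet or tweet.text.lstrip().startswith(RETWEET_MARKER)


def drop_retweets(corpus: Corpus) -> Corpus:
    return corpus.with_tweets(t for t in corpus.tweets if not is_retweet(t))


def filter_language(corpus: Corpus, lang: str = "es") -> Corpus:
    """Keep tweets whose language code equals ``lang`` exactly."""
    return corpus.with_tweets(t for t in corpus.tweets if t.lang == lang)


def truncate_timeline(tweets: Sequence[Tweet], cap: int = 3200) -> list[Tweet]:
    """Keep at most ``cap`` most-recent tweets of one user's timeline.

    The input must already be sorted most-recent-first; an unsorted input is
    a caller bug and raises.
    """
    if cap < 0:
        raise ValueError("cap must be non-negative")
    times = [t.created_at_utc for t in tweets]
    if any(a < b for a, b in zip(times, times[1:])):
        raise ValueError("timeline not sorted most-recent-first")
    return list(tweets[:cap])


__all__ = [
    "Tweet",
    "UserProfile",
    "Corpus",
    "DATASET_LABELS",
    "DEFAULT_SCHEMA",
    "read_corpus",
    "write_corpus",
    "parse_timestamp",
    "is_retweet",
    "drop_retweets",
    "filter_language",
    "truncate_timeline",
]
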