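"""User-selection and dataset-assembly rules.

The study design: users whose profile description mentions ``depr``-derived
words and whose timeline contains at least ``min_flagged`` hand-flagged
depressive tweets form the depressive cohort; a random sample of users whose
profiles do not mention those words forms the control cohort.  Three
pairwise-disjoint corpora are then assembled:

* ``depressive_tweets`` — exactly the flagged tweets,
* ``depressive_users``  — the cohort's timelines minus flagged tweets minus
  retweets,
* ``control``           — the control timelines minus retweets.
"""

from __future__ import annotations

import logging
import unicodedata
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import _vocabulary as vocab
from .corpus_io import Corpus, Tweet, UserProfile, is_retweet
from .tokenizer import tokenize_tweet, words

log = logging.getLogger("tuitvig")

DEFAULT_MIN_FLAGGED = 10


def load_term_list(path: str | Path) -> list[str]:
    """One lower-case term per line, UTF-8, blank lines ignored."""
    out = [
        line.strip().lower()
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if line.strip()
    ]
    return out


@dataclass(frozen=True)
class KeywordList:
    """Lemma patterns; a trailing ``/a`` marks a masc/fem variant pair."""

    entries: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("empty keyword list")
        if any(e != e.lower() for e in self.entries):
            raise ValueError("keyword entries must be lower-case")

    @classmethod
    def bundled(cls) -> "KeywordList":
        return cls(tuple(vocab.DEPRESSION_KEYWORDS))

    @classmethod
    def from_file(cls, path: str | Path) -> "KeywordList":
        return cls(tuple(load_term_list(path)))

    def expansion(self) -> dict[str, str]:
        """Surface form -> canonical entry ('agobiada' -> 'agobiado/a')."""
        table: dict[str, str] = {}
        for entry in self.entries:
            for form in vocab.expand_keyword(entry):
                table[form] = entry
        return table


@dataclass(frozen=True)
class ScreeningDecision:
    user_id: str
    profile_matched: bool
    matched_derivations: tuple[str, ...] = ()
    flagged_tweet_count: int = 0
    retained: bool = False

    def __post_init__(self) -> None:
        if self.retained and not (self.profile_matched and self.flagged_tweet_count >= 1):
            raise ValueError("retained user must match profile and have flagged tweets")


def match_keywords(text: str, keywords: KeywordList) -> set[str]:
    """Canonical keyword entries whose forms occur as word tokens of ``text``.

    Matching is case-insensitive but accent-sensitive (the screening terms
    are accented; see :func:`profile_mentions_depr` for the one documented
    relaxation).
    """
    table = keywords.expansion()
    return {table[w] for w in words(tokenize_tweet(text)) if w in table}


def _strip_accents(s: str) -> str:
    return "".join(
        c for c in unicodedata.normalize("NFD", s) if unicodedata.category(c) != "Mn"
    )


def profile_mentions_depr(
    description: str,
    derivations: Sequence[str] | None = None,
    accent_relaxed: bool = True,
) -> tuple[bool, set[str]]:
    """Does a profile description mention depression?

    Token-level, case-insensitive match against the closed derivation set
    (``depre, depresión, depresivo, depresiva, deprimido, deprimida``).
    With ``accent_relaxed`` (default) the unaccented spelling ``depresion``
    also matches ``depresión`` — users frequently drop exactly that accent.
    """
    derivs = list(derivations) if derivations is not None else list(vocab.DEPR_DERIVATIONS)
    table = {d: d for d in derivs}
    if accent_relaxed:
        for d in derivs:
            table.setdefault(_strip_accents(d), d)
    matched = {table[w] for w in words(tokenize_tweet(description)) if w in table}
    return bool(matched), matched


def retain_depressive_user(
    user_id: str,
    profile_matched: bool,
    flagged_tweet_count: int,
    matched_derivations: Iterable[str] = (),
    threshold: int = DEFAULT_MIN_FLAGGED,
) -> ScreeningDecision:
    """Retention rule: profile matched AND >= ``threshold`` flagged tweets."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    retained = profile_matched and flagged_tweet_count >= threshold
    return ScreeningDecision(
        user_id=user_id,
        profile_matched=profile_matched,
        matched_derivations=tuple(sorted(matched_derivations)),
        flagged_tweet_count=flagged_tweet_count,
        retained=retained,
    )


def screen_users(
    profiles: Mapping[str, UserProfile],
    flagged_counts: Mapping[str, int],
    threshold: int = DEFAULT_MIN_FLAGGED,
    vetted: Mapping[str, bool] | None = None,
) -> dict[str, ScreeningDecision]:
    """Apply profile matching + retention to a set of users.

    ``vetted`` stands in for the clinical judgment that excluded quotes,
    jokes and fake statements; absent entries default to True.
    """
    out = {}
    for uid, prof in profiles.items():
        ok, matched = profile_mentions_depr(prof.description)
        if vetted is not None and not vetted.get(uid, True):
            ok, matched = False, set()
        out[uid] = retain_depressive_user(
            uid, ok, flagged_counts.get(uid, 0), matched, threshold
        )
    return out


def sample_control_users(
    pool: Sequence[str],
    n: int,
    exclusions: Iterable[str] = (),
    seed: int = 0,
    profiles: Mapping[str, UserProfile] | None = None,
) -> list[str]:
    """Uniform sample without replacement, reproducible given ``seed``.

    Users in ``exclusions`` — and, when ``profiles`` is given, users whose
    profile mentions depression — are never sampled.
    """
    excluded = set(exclusions)
    if profiles is not None:
        excluded |= {
            uid
            for uid, prof in profiles.items()
            if profile_mentions_depr(prof.description)[0]
        }
    eligible = [u for u in pool if u not in excluded]
    if len(eligible) < n:
        raise ValueError(f"pool of {len(eligible)} eligible users < requested {n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n, replace=False)
    return [eligible[i] for i in sorted(idx)]


def assemble_datasets(
    depressive_timelines: Mapping[str, Sequence[Tweet]],
    flagged_tweet_ids: Iterable[str],
    control_timelines: Mapping[str, Sequence[Tweet]],
    profiles: Mapping[str, UserProfile] | None = None,
) -> tuple[Corpus, Corpus, Corpus]:
    """Build the three pairwise-disjoint corpora.

    Returns ``(control, depressive_users, depressive_tweets)``.  Flagged
    tweets are pulled out of the depressive timelines before retweet
    removal; a flagged id absent from those timelines is an error.
    """
    profiles = dict(profiles or {})
    flagged_ids = set(flagged_tweet_ids)

    dep_all = [t for tl in depressive_timelines.values() for t in tl]
    by_id = {t.tweet_id: t for t in dep_all}
    missing = flagged_ids - set(by_id)
    if missing:
        raise ValueError(f"{len(missing)} flagged ids not found in depressive timelines")

    flagged = [t for t in dep_all if t.tweet_id in flagged_ids]
    dep_rest = [
        t for t in dep_all if t.tweet_id not in flagged_ids and not is_retweet(t)
    ]
    ctrl = [
        t for tl in control_timelines.values() for t in tl if not is_retweet(t)
    ]

    def profs(tweets: list[Tweet]) -> dict[str, UserProfile]:
        return {
            t.user_id: profiles.get(t.user_id, UserProfile(t.user_id))
            for t in tweets
        }

    control = Corpus("control", ctrl, profs(ctrl))
    dep_users = Corpus("depressive_users", dep_rest, profs(dep_rest))
    dep_tweets = Corpus("depressive_tweets", flagged, profs(flagged))
    log.info(
        "assembled datasets: control=%d depressive_users=%d depressive_tweets=%d",
        len(control), len(dep_users), len(dep_tweets),
    )
    return control, dep_users, dep_tweets


__all__ = [
    "KeywordList",
    "ScreeningDecision",
    "DEFAULT_MIN_FLAGGED",
    "load_term_list",
    "match_keywords",
    "profile_mentions_depr",
    "retain_depressive_user",
    "screen_users",
    "sample_control_users",
    "assemble_datasets",
]
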