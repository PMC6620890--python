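"""Timezone-adjusted diurnal and weekly activity profiles.

Tweet times are stored in UTC; each user's declared UTC offset shifts them
into local time before binning.  Activity is normalised per user — mean
tweets per bin per observed local day — before group means and standard
errors are taken across users, so heavy posters do not dominate the group
profile.  Tweets without a UTC offset are dropped from temporal analyses
(logged); retweets are excluded by default to match the rest of the
pipeline, with a flag to include them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import timedelta
from typing import Mapping

import numpy as np

from .corpus_io import Corpus, Tweet, is_retweet

log = logging.getLogger("tuitvig")

WEEKDAYS = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")


def local_time(tweet: Tweet) -> tuple[int, int] | None:
    """(hour 0-23, ISO weekday index 0=Mon..6=Sun) in the user's zone.

    Returns None when the tweet carries no UTC offset (default policy:
    exclude from temporal analyses).
    """
    if tweet.utc_offset_seconds is None:
        return None
    local = tweet.created_at_utc + timedelta(seconds=tweet.utc_offset_seconds)
    return local.hour, local.weekday()


@dataclass
class TemporalProfile:
    """Per-user mean activity per bin, plus the group mean ± SEM."""

    bins: tuple  # bin labels (24 hours or 7 weekday names)
    user_ids: list[str]
    per_user: np.ndarray  # shape (n_users, n_bins): mean tweets/bin/day
    mean: np.ndarray  # group mean per bin
    sem: np.ndarray  # sample SD / sqrt(n_users) per bin

    @property
    def n_users(self) -> int:
        return len(self.user_ids)


def _profile(
    corpus: Corpus, n_bins: int, bin_of: Mapping[int, int] | None, mode: str,
    include_retweets: bool,
) -> TemporalProfile:
    """Shared hourly/weekday implementation.

    Per user: (tweets in bin) / (number of distinct local days on which the
    user tweeted), then mean and SEM across users per bin.
    """
    per_user: dict[str, np.ndarray] = {}
    days: dict[str, set] = {}
    n_dropped = 0
    for t in corpus.tweets:
        if not include_retweets and is_retweet(t):
            continue
        lt = local_time(t)
        if lt is None:
            n_dropped += 1
            continue
        hour, weekday = lt
        local = t.created_at_utc + timedelta(seconds=t.utc_offset_seconds or 0)
        vec = per_user.setdefault(t.user_id, np.zeros(n_bins))
        vec[hour if mode == "hour" else weekday] += 1
        days.setdefault(t.user_id, set()).add(local.date())
    if n_dropped:
        log.info("temporal: dropped %d tweets without utc offset", n_dropped)
    if not per_user:
        raise ValueError("no temporally-valid tweets in corpus")
    user_ids = sorted(per_user)
    mat = np.vstack([per_user[u] / len(days[u]) for u in user_ids])
    mean = mat.mean(axis=0)
    if len(user_ids) > 1:
        sem = mat.std(axis=0, ddof=1) / np.sqrt(len(user_ids))
    else:
        sem = np.zeros(n_bins)
    bins = tuple(range(24)) if mode == "hour" else WEEKDAYS
    return TemporalProfile(bins, user_ids, mat, mean, sem)


def hourly_profile(corpus: Corpus, include_retweets: bool = False) -> TemporalProfile:
    """24-bin local-hour activity profile."""
    return _profile(corpus, 24, None, "hour", include_retweets)


def weekday_profile(corpus: Corpus, include_retweets: bool = False) -> TemporalProfile:
    """7-bin Monday-first weekday activity profile."""
    return _profile(corpus, 7, None, "weekday", include_retweets)


def night_fraction(corpus: Corpus, start: int = 23, end: int = 6,
                   include_retweets: bool = False) -> tuple[int, int]:
    """(tweets in the night window [start, 24) ∪ [0, end), total valid).

    The default window 23:00-06:00 is the span over which depressive and
    control activity levels converge in the motivating comparison.
    """
    n_night = n_total = 0
    for t in corpus.tweets:
        if not include_retweets and is_retweet(t):
            continue
        lt = local_time(t)
        if lt is None:
            continue
        hour, _ = lt
        n_total += 1
        if hour >= start or hour < end:
            n_night += 1
    return n_night, n_total


def weekend_fraction(corpus: Corpus, include_retweets: bool = False) -> tuple[int, int]:
    """(tweets on Sat/Sun, total valid)."""
    n_we = n_total = 0
    for t in corpus.tweets:
        if not include_retweets and is_retweet(t):
            continue
        lt = local_time(t)
        if lt is None:
            continue
        _, weekday = lt
        n_total += 1
        if weekday >= 5:
            n_we += 1
    return n_we, n_total


__all__ = [
    "WEEKDAYS",
    "TemporalProfile",
    "local_time",
    "hourly_profile",
    "weekday_profile",
    "night_fraction",
    "weekend_fraction",
]
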