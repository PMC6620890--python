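"""Shared fixtures: a small synthetic study and handy builders."""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

import pytest

from tuitvig import synthetic
from tuitvig.corpus_io import Corpus, Tweet, UserProfile


def make_tweet(
    tweet_id: str = "t1",
    user_id: str = "u1",
    text: str = "hola mundo",
    when: datetime | None = None,
    offset: int | None = 7200,
    is_retweet: bool = False,
    lang: str = "es",
) -> Tweet:
    return Tweet(
        tweet_id=tweet_id,
        user_id=user_id,
        text=text,
        created_at_utc=when or datetime(2018, 3, 14, 12, 0, tzinfo=timezone.utc),
        utc_offset_seconds=offset,
        is_retweet=is_retweet,
        lang=lang,
    )


def make_corpus(texts: list[str], label: str = "control", **kw) -> Corpus:
    base = datetime(2018, 3, 14, 12, 0, tzinfo=timezone.utc)
    tweets = [
        make_tweet(f"t{i}", "u1", text, when=base + timedelta(minutes=i), **kw)
        for i, text in enumerate(texts)
    ]
    return Corpus(label, tweets, {"u1": UserProfile("u1")})


@pytest.fixture(scope="session")
def small_study() -> synthetic.StudyData:
    """~2000 analyzed tweets per population; shared across test modules."""
    specs = {
        "control": synthetic.control_spec(),
        "depressive": synthetic.depressive_spec(),
    }
    scaled = {
        name: spec.scaled(int(2000 / (1 - spec.retweet_rate)))
        for name, spec in specs.items()
    }
    return synthetic.generate_study(
        control=scaled["control"], depressive=scaled["depressive"], seed=11
    )


@pytest.fixture(scope="session")
def bank() -> synthetic.VocabularyBank:
    return synthetic.build_vocabulary(0)
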