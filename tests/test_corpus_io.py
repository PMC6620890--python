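"""Corpus reading, validation and the screening-stage filters."""

import json
from datetime import datetime, timedelta, timezone

import pytest

from tuitvig.corpus_io import (
    Corpus,
    Tweet,
    drop_retweets,
    filter_language,
    is_retweet,
    read_corpus,
    truncate_timeline,
    write_corpus,
)
from conftest import make_corpus, make_tweet


def _jsonl_line(i: int, text: str = "hola que tal") -> str:
    return json.dumps(
        {
            "id_str": f"id{i}",
            "user": {"id_str": "u1", "utc_offset": 7200, "description": "perfil"},
            "full_text": text,
            "created_at": "Wed Jun 13 20:08:51 +0000 2018",
            "is_retweet": False,
            "lang": "es",
        }
    )


class TestReadCorpus:
    def test_well_formed_lines_become_tweets(self, tmp_path):
        p = tmp_path / "c.jsonl"
        p.write_text("\n".join(_jsonl_line(i) for i in range(3)) + "\n")
        corpus = read_corpus(p)
        assert len(corpus) == 3
        assert corpus.tweets[0].created_at_utc == datetime(
            2018, 6, 13, 20, 8, 51, tzinfo=timezone.utc
        )

    def test_empty_file_gives_empty_corpus(self, tmp_path):
        p = tmp_path / "empty.jsonl"
        p.write_text("")
        assert len(read_corpus(p)) == 0

    def test_truncated_line_skipped_and_counted(self, tmp_path):
        p = tmp_path / "c.jsonl"
        p.write_text(_jsonl_line(0) + "\n" + _jsonl_line(1)[:25] + "\n" + _jsonl_line(2) + "\n")
        corpus = read_corpus(p)
        assert len(corpus) == 2
        assert corpus.skipped_lines == 1

    def test_mostly_malformed_file_is_fatal(self, tmp_path):
        p = tmp_path / "bad.jsonl"
        p.write_text("{broken\n{also broken\n" + _jsonl_line(0) + "\n")
        with pytest.raises(ValueError, match="malformed"):
            read_corpus(p)

    def test_duplicate_ids_deduplicated(self, tmp_path):
        p = tmp_path / "dup.jsonl"
        p.write_text(_jsonl_line(0) + "\n" + _jsonl_line(0) + "\n")
        assert len(read_corpus(p)) == 1

    def test_round_trip_identity(self, tmp_path, small_study):
        corpus = Corpus("control", small_study.control.tweets[:50],
                        small_study.control.profiles)
        path = tmp_path / "rt.jsonl"
        write_corpus(corpus, path)
        back = read_corpus(path, label="control")
        assert [t.tweet_id for t in back.tweets] == [t.tweet_id for t in corpus.tweets]
        assert [t.text for t in back.tweets] == [t.text for t in corpus.tweets]
        assert [t.created_at_utc for t in back.tweets] == [
            t.created_at_utc for t in corpus.tweets
        ]


class TestTweetValidation:
    def test_empty_text_rejected(self):
        with pytest.raises(ValueError, match="empty text"):
            make_tweet(text="   ")

    def test_offset_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            make_tweet(offset=60_000)


class TestRetweetFilter:
    def test_no_retweets_unchanged(self):
        c = make_corpus(["hola", "adiós"])
        assert len(drop_retweets(c)) == 2

    def test_flagged_retweets_removed(self):
        c = make_corpus(["a b", "c d", "e f"])
        c.tweets[0] = make_tweet("t0", text="x y", is_retweet=True)
        c.tweets[1] = make_tweet("t1", text="z w", is_retweet=True)
        assert len(drop_retweets(c)) == 1

    def test_rt_marker_removed_even_without_flag(self):
        c = make_corpus(["RT @x hola", "hola RT"])
        kept = drop_retweets(c)
        assert [t.text for t in kept.tweets] == ["hola RT"]

    def test_idempotent_and_conserving(self):
        c = make_corpus(["RT @x hola", "normal", "  RT @y eco"])
        once = drop_retweets(c)
        assert len(once) + sum(is_retweet(t) for t in c.tweets) == len(c)
        assert [t.tweet_id for t in drop_retweets(once).tweets] == [
            t.tweet_id for t in once.tweets
        ]


class TestLanguageFilter:
    def test_exact_code_match(self):
        c = make_corpus(["hola"] * 6 + ["hello"] * 4)
        for i in range(6, 10):
            c.tweets[i] = make_tweet(f"t{i}", text="hello", lang="en")
        assert len(filter_language(c, "es")) == 6
        assert len(filter_language(c, "en")) == 4

    def test_idempotent(self):
        c = make_corpus(["hola", "hey"])
        c.tweets[1] = make_tweet("t1", text="hey", lang="en")
        once = filter_language(c, "es")
        assert [t.tweet_id for t in filter_language(once, "es").tweets] == [
            t.tweet_id for t in once.tweets
        ]


class TestTruncateTimeline:
    def _timeline(self, n: int) -> list[Tweet]:
        base = datetime(2018, 6, 1, tzinfo=timezone.utc)
        return [
            make_tweet(f"t{i}", when=base - timedelta(hours=i)) for i in range(n)
        ]

    def test_under_cap_unchanged(self):
        assert len(truncate_timeline(self._timeline(10), 3200)) == 10

    def test_cap_keeps_most_recent(self):
        tl = self._timeline(40)
        kept = truncate_timeline(tl, 30)
        assert len(kept) == 30
        assert kept[0].created_at_utc == tl[0].created_at_utc
        assert min(t.created_at_utc for t in kept) > tl[35].created_at_utc

    def test_cap_zero_empties(self):
        assert truncate_timeline(self._timeline(5), 0) == []

    def test_unsorted_input_rejected(self):
        tl = self._timeline(5)[::-1]
        with pytest.raises(ValueError, match="sorted"):
            truncate_timeline(tl, 3)
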