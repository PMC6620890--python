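"""Keyword matching, profile screening and dataset assembly rules."""

import pytest
from hypothesis import given, settings, strategies as st

from tuitvig.corpus_io import UserProfile
from tuitvig.screening import (
    KeywordList,
    assemble_datasets,
    match_keywords,
    profile_mentions_depr,
    retain_depressive_user,
    sample_control_users,
    screen_users,
)
from conftest import make_tweet


KW = KeywordList.bundled()


class TestMatchKeywords:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("estoy muy triste hoy", {"triste"}),
            ("hoy hace sol", set()),
            ("agobiada y cansada", {"agobiado/a", "cansado/a"}),
            ("¡TRISTE!", {"triste"}),  # case + punctuation invariance
            ("tristeza", set()),  # token-level, not substring
            ("vacía por dentro", {"vacío/a"}),
        ],
    )
    def test_examples(self, text, expected):
        assert match_keywords(text, KW) == expected

    def test_accent_sensitive(self):
        # the keyword is "depresión"; the bare unaccented form is not a hit
        assert match_keywords("depresion", KW) == set()
        assert match_keywords("depresión", KW) == {"depresión"}

    def test_empty_keyword_list_rejected(self):
        with pytest.raises(ValueError):
            KeywordList(())


class TestProfileMatch:
    @pytest.mark.parametrize(
        "desc, expect_hit, expect_terms",
        [
            ("Paciente psiquiátrico con depresión crónica", True, {"depresión"}),
            ("", False, set()),
            ("DEPRE total", True, {"depre"}),
            ("depresion sin tilde", True, {"depresión"}),
            ("la depresión económica", True, {"depresión"}),
            ("me deprimo a veces", False, set()),  # not in the closed set
        ],
    )
    def test_examples(self, desc, expect_hit, expect_terms):
        hit, terms = profile_mentions_depr(desc)
        assert hit is expect_hit
        assert terms == expect_terms

    def test_accent_relaxation_can_be_disabled(self):
        hit, _ = profile_mentions_depr("depresion", accent_relaxed=False)
        assert not hit


class TestRetention:
    @pytest.mark.parametrize(
        "matched, flagged, retained",
        [(True, 10, True), (True, 9, False), (False, 50, False), (True, 0, False)],
    )
    def test_threshold_rule(self, matched, flagged, retained):
        d = retain_depressive_user("u", matched, flagged)
        assert d.retained is retained

    @given(
        flagged=st.integers(min_value=0, max_value=60),
        low=st.integers(min_value=1, max_value=30),
        high=st.integers(min_value=1, max_value=30),
    )
    @settings(max_examples=60, deadline=None)
    def test_raising_threshold_never_adds_users(self, flagged, low, high):
        low, high = sorted((low, high))
        at_low = retain_depressive_user("u", True, flagged, threshold=low).retained
        at_high = retain_depressive_user("u", True, flagged, threshold=high).retained
        assert at_low or not at_high  # retained at high => retained at low


class TestControlSampling:
    def test_sample_size_and_determinism(self):
        pool = [f"u{i}" for i in range(1000)]
        s1 = sample_control_users(pool, 450, seed=3)
        s2 = sample_control_users(pool, 450, seed=3)
        assert len(s1) == len(set(s1)) == 450
        assert s1 == s2
        assert s1 != sample_control_users(pool, 450, seed=4)

    def test_depression_profiles_excluded(self):
        pool = ["a", "b", "c", "d"]
        profiles = {
            "a": UserProfile("a", "vivo con depresión"),
            "b": UserProfile("b", "me gusta el cine"),
            "c": UserProfile("c", "depre perpetua"),
            "d": UserProfile("d", ""),
        }
        got = sample_control_users(pool, 2, seed=0, profiles=profiles)
        assert set(got) == {"b", "d"}

    def test_insufficient_pool_is_error(self):
        with pytest.raises(ValueError, match="pool"):
            sample_control_users(["a", "b"], 3)

    def test_n_zero_gives_empty(self):
        assert sample_control_users(["a", "b"], 0) == []


class TestScreenUsers:
    def test_vetting_overrides_profile_match(self):
        profiles = {
            "u1": UserProfile("u1", "con depresión desde 2010"),
            "u2": UserProfile("u2", "tuits depresivos irónicos"),
        }
        decisions = screen_users(
            profiles, {"u1": 12, "u2": 30}, vetted={"u2": False}
        )
        assert decisions["u1"].retained
        assert not decisions["u2"].retained


class TestAssembleDatasets:
    def _fixture(self):
        dep_tl, flagged = {}, []
        k = 0
        for u in range(5):
            uid = f"d{u}"
            tweets = []
            for i in range(8):
                is_rt = i % 4 == 3  # 2 retweets per user
                t = make_tweet(f"dep{k}", uid, "RT @z eco" if is_rt else "texto normal",
                               is_retweet=is_rt)
                tweets.append(t)
                k += 1
            dep_tl[uid] = tweets
        # 7 flagged among non-retweets
        non_rt = [t for tl in dep_tl.values() for t in tl if not t.is_retweet]
        flagged = [t.tweet_id for t in non_rt[:7]]
        ctrl_tl = {
            "c0": [make_tweet(f"ctl{i}", "c0", "hola") for i in range(6)],
        }
        return dep_tl, flagged, ctrl_tl

    def test_disjoint_and_conserving(self):
        dep_tl, flagged, ctrl_tl = self._fixture()
        control, dep_users, dep_tweets = assemble_datasets(dep_tl, flagged, ctrl_tl)
        ids = [
            {t.tweet_id for t in c.tweets} for c in (control, dep_users, dep_tweets)
        ]
        assert not (ids[0] & ids[1]) and not (ids[0] & ids[2]) and not (ids[1] & ids[2])
        non_rt_total = sum(
            1 for tl in dep_tl.values() for t in tl if not t.is_retweet
        )
        assert len(dep_users) + len(dep_tweets) == non_rt_total
        assert len(dep_tweets) == 7

    def test_zero_flagged_gives_empty_tweets_dataset(self):
        dep_tl, _, ctrl_tl = self._fixture()
        _, _, dep_tweets = assemble_datasets(dep_tl, [], ctrl_tl)
        assert len(dep_tweets) == 0

    def test_unknown_flagged_id_is_error(self):
        dep_tl, _, ctrl_tl = self._fixture()
        with pytest.raises(ValueError, match="flagged"):
            assemble_datasets(dep_tl, ["nope"], ctrl_tl)
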