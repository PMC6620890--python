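"""Generator determinism, vocabulary alignment and ground-truth bookkeeping."""

from tuitvig import synthetic
from tuitvig._vocabulary import pos_inventories
from tuitvig.lexicons import (
    EmotionLexicon,
    NegationLexicon,
    PolarityLexicon,
)
from tuitvig.screening import profile_mentions_depr, screen_users
from tuitvig.tagging import DictionaryTagger, pos_profile
from tuitvig.temporal import local_time


class TestVocabularyBank:
    def test_deterministic(self):
        assert synthetic.build_vocabulary(1) == synthetic.build_vocabulary(1)

    def test_every_lexicon_term_resolvable_by_tagger(self, bank):
        tagger = DictionaryTagger.bundled()
        terms = set(NegationLexicon.bundled().terms)
        terms |= set(EmotionLexicon.bundled().entries)
        terms |= set(PolarityLexicon.bundled_binary().entries)
        terms |= set(PolarityLexicon.bundled_graded().entries)
        terms |= set(bank.keyword_forms)
        unresolved = {t for t in terms if tagger(t)[0] == "other"}
        assert unresolved == set()

    def test_pos_inventories_disjoint(self):
        inv = pos_inventories()
        cats = list(inv)
        for i, a in enumerate(cats):
            for b in cats[i + 1:]:
                assert not set(inv[a]) & set(inv[b]), (a, b)

    def test_neutral_pools_carry_no_annotations(self, bank):
        annotated = set(NegationLexicon.bundled().terms)
        annotated |= set(EmotionLexicon.bundled().entries)
        annotated |= set(PolarityLexicon.bundled_binary().entries)
        annotated |= set(PolarityLexicon.bundled_graded().entries)
        annotated |= set(bank.keyword_forms)
        for pool in bank.neutral.values():
            assert not set(pool) & annotated


def _tiny_spec(**overrides):
    spec = synthetic.control_spec()
    base = dict(n_users=4, tweets_per_user_mean=40.0)
    base.update(overrides)
    import dataclasses

    return dataclasses.replace(spec, **base)


class TestGenerateUser:
    def test_all_mass_on_one_hour(self, bank):
        weights = [0.0] * 24
        weights[3] = 1.0
        spec = _tiny_spec(hourly_weights=tuple(weights), retweet_rate=0.0)
        _, tweets, _ = synthetic.generate_user(spec, bank, 0, seed=5)
        assert all(local_time(t)[0] == 3 for t in tweets)

    def test_zero_negation_rate_gives_zero_negations(self, bank):
        spec = _tiny_spec(negation_rate=0.0, retweet_rate=0.0)
        _, tweets, truths = synthetic.generate_user(spec, bank, 0, seed=5)
        neg = NegationLexicon.bundled()
        from tuitvig.lexicons import detect_negations
        from tuitvig.tokenizer import tokenize_tweet

        assert all(t.negations == 0 for t in truths)
        assert all(detect_negations(tokenize_tweet(t.text), neg) == 0 for t in tweets)

    def test_substreams_reproducible(self, bank):
        spec = _tiny_spec()
        a = synthetic.generate_user(spec, bank, 2, seed=9)
        b = synthetic.generate_user(spec, bank, 2, seed=9)
        assert [t.text for t in a[1]] == [t.text for t in b[1]]
        assert [t.created_at_utc for t in a[1]] == [t.created_at_utc for t in b[1]]


class TestGenerateStudy:
    def test_same_seed_byte_identical_files(self, tmp_path, bank):
        kw = dict(
            control=_tiny_spec(), depressive=_tiny_spec(), seed=3,
            flagged_fraction=0.05, min_flagged_per_user=2,
        )
        for d in ("a", "b"):
            synthetic.generate_study(**kw).write(tmp_path / d)
        for name in ("control.jsonl", "depressive_users.jsonl",
                     "depressive_tweets.jsonl", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_zero_flagged_fraction_empties_tweets_dataset(self):
        study = synthetic.generate_study(
            control=_tiny_spec(), depressive=_tiny_spec(), flagged_fraction=0.0,
            seed=4,
        )
        assert len(study.depressive_tweets) == 0

    def test_corpora_disjoint_and_retweet_free(self, small_study):
        ids = [
            {t.tweet_id for t in c.tweets}
            for c in small_study.corpora().values()
        ]
        assert not ids[0] & ids[1] and not ids[0] & ids[2] and not ids[1] & ids[2]
        from tuitvig.corpus_io import is_retweet

        assert not any(is_retweet(t) for t in small_study.control.tweets)
        assert not any(is_retweet(t) for t in small_study.depressive_users.tweets)

    def test_pos_truth_matches_pipeline_exactly(self, small_study):
        # dictionary tagging introduces no noise: measured == bookkept
        for label, corpus in small_study.corpora().items():
            measured = pos_profile(corpus).counts
            assert measured == small_study.truth["datasets"][label]["pos_counts"], label

    def test_flagged_tweets_carry_screening_keywords(self, small_study):
        from tuitvig.screening import KeywordList, match_keywords

        kw = KeywordList.bundled()
        hits = [
            bool(match_keywords(t.text, kw))
            for t in small_study.depressive_tweets.tweets
        ]
        assert all(hits)

    def test_noun_contrast_direction_matches_presets(self, small_study):
        ctrl = pos_profile(small_study.control).percentages()["noun"]
        dep = pos_profile(small_study.depressive_users).percentages()["noun"]
        assert ctrl > dep

    def test_screening_recovers_depressive_population(self, small_study):
        corpora = small_study.corpora()
        profiles = {}
        for c in corpora.values():
            profiles.update(c.profiles)
        flagged_counts = {}
        for t in small_study.depressive_tweets.tweets:
            flagged_counts[t.user_id] = flagged_counts.get(t.user_id, 0) + 1
        decisions = screen_users(profiles, flagged_counts, threshold=10)
        retained = {u for u, d in decisions.items() if d.retained}
        depressive = set(small_study.depressive_users.user_ids())
        assert retained == depressive

    def test_control_profiles_never_mention_depression(self, small_study):
        for uid in small_study.control.user_ids():
            desc = small_study.control.profiles[uid].description
            assert not profile_mentions_depr(desc)[0]
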