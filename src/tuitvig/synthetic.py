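"""Two-population synthetic tweet corpora with known structure.

The generator emits token-sequence "tweets" (not grammatical Spanish) drawn
from the bundled vocabulary, so every downstream measurement — POS shares,
pronoun persons, emotion/negation/polarity rates, activity profiles — has an
exactly bookkept ground truth.  Default population presets encode the
contrasts reported for control vs depressive Twitter cohorts: depressive
users post less, relatively more at night and flatter across the week, use
fewer nouns and more verbs/pronouns/adverbs, more first-person-singular
pronouns, more sadness/anger/disgust words, more negations, more negative
polarity, and write shorter tweets.

All randomness flows from one integer seed; each user gets an independent
substream derived from (seed, population, user index), so corpora are
byte-reproducible and order-independent.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field, asdict, replace
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import _vocabulary as vocab
from .corpus_io import Corpus, Tweet, UserProfile, write_corpus
from .screening import assemble_datasets
from .tagging import POS_CATEGORIES, PRONOUN_PERSONS
from .lexicons import EMOTIONS

#: 180-day observation window starting on a Monday.
WINDOW_START = datetime(2018, 1, 1, tzinfo=timezone.utc)
WINDOW_DAYS = 180

POLARITY_CELLS = ("positive", "negative", "graded", "none")
ENTITY_KINDS = ("hashtag", "link", "mention", "emoji")

_EMOJI_SET = ("😢", "😀", "😂", "❤️", "😡", "🙏", "👍", "🌙")
_HASHTAG_TOPICS = ("futbol", "musica", "series", "noticias", "finde", "lunes")


# ---------------------------------------------------------------------------
# Vocabulary bank


@dataclass(frozen=True)
class VocabularyBank:
    """Per-category word inventories aligned with the bundled resources.

    ``neutral`` holds words free of any lexicon annotation (generator
    filler); injection pools are single-annotation by construction so each
    injected token is attributable to exactly one measured rate.
    """

    neutral: Mapping[str, tuple[str, ...]]
    personal_pronouns: Mapping[str, tuple[str, ...]]
    negation_words: tuple[str, ...]
    emotion_pools: Mapping[str, tuple[str, ...]]
    binary_positive: tuple[str, ...]
    binary_negative: tuple[str, ...]
    graded_pools: Mapping[tuple[int, str], tuple[str, ...]]  # (sign, strength)
    keyword_forms: tuple[str, ...]
    word_pos: Mapping[str, str]


def build_vocabulary(seed: int = 0) -> VocabularyBank:
    """Deterministic bank; ``seed`` is accepted for interface symmetry."""
    inventories = vocab.pos_inventories()
    word_pos = {w: pos for pos, inv in inventories.items() for w in inv}

    annotated = set(vocab.NEGATIONS)
    annotated |= {t for t, _ in vocab.emotion_lexicon_rows()}
    annotated |= set(vocab.BINARY_POSITIVE) | set(vocab.BINARY_NEGATIVE)
    annotated |= set(vocab.GRADED_ENTRIES)
    keyword_forms = tuple(
        sorted(
            {f for kw in vocab.DEPRESSION_KEYWORDS for f in vocab.expand_keyword(kw)}
        )
    )
    annotated |= set(keyword_forms)
    person_words = {w for forms in vocab.PERSONAL_PRONOUNS.values() for w in forms}

    neutral = {}
    for pos, inv in inventories.items():
        if pos == "pronoun":
            pool = [w for w in inv if w not in annotated and w not in person_words]
        else:
            pool = [w for w in inv if w not in annotated]
        neutral[pos] = tuple(pool)

    graded_pools: dict[tuple[int, str], tuple[str, ...]] = {}
    for sign in (1, -1):
        for strength, cutoff in (("strong", 0.5), ("moderate", 0.0)):
            terms = [
                t
                for t, v in vocab.GRADED_ENTRIES.items()
                if np.sign(v) == sign
                and (abs(v) >= 0.5) == (strength == "strong")
            ]
            graded_pools[(sign, strength)] = tuple(sorted(terms))

    multi = set(vocab.MULTI_EMOTION_TERMS)
    emotion_pools = {
        emo: tuple(t for t in terms if t not in multi)
        for emo, terms in vocab.EMOTION_TERMS.items()
    }
    return VocabularyBank(
        neutral={k: tuple(v) for k, v in neutral.items()},
        personal_pronouns={k: tuple(v) for k, v in vocab.PERSONAL_PRONOUNS.items()},
        negation_words=tuple(vocab.NEGATIONS),
        emotion_pools=emotion_pools,
        binary_positive=tuple(vocab.BINARY_POSITIVE),
        binary_negative=tuple(vocab.BINARY_NEGATIVE),
        graded_pools=graded_pools,
        keyword_forms=keyword_forms,
        word_pos=word_pos,
    )


# ---------------------------------------------------------------------------
# Population specification


def _norm(v: Sequence[float]) -> tuple[float, ...]:
    arr = np.asarray(v, dtype=float)
    if (arr < 0).any() or arr.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    return tuple(arr / arr.sum())


@dataclass(frozen=True)
class PopulationSpec:
    """Everything that defines one synthetic population."""

    name: str
    n_users: int
    tweets_per_user_mean: float
    tweets_per_user_dispersion: float  # negative-binomial shape k
    retweet_rate: float
    hourly_weights: tuple[float, ...]
    weekday_weights: tuple[float, ...]
    pos_mixture: tuple[float, ...]  # over POS_CATEGORIES
    pronoun_mixture: tuple[float, ...]  # over PRONOUN_PERSONS
    emotion_rates: Mapping[str, float]  # per-tweet Bernoulli rates
    negation_rate: float  # Poisson mean per tweet
    polarity_mixture: tuple[float, ...]  # over POLARITY_CELLS
    graded_negative_fraction: float
    entity_rates: Mapping[str, float]  # per-tweet Bernoulli rates
    length_mean: float  # filler tokens per tweet (truncated normal >= 1)
    length_sd: float
    utc_offset_seconds: int
    profile_templates: tuple[str, ...]
    lang: str = "es"

    def __post_init__(self) -> None:
        object.__setattr__(self, "hourly_weights", _norm(self.hourly_weights))
        object.__setattr__(self, "weekday_weights", _norm(self.weekday_weights))
        object.__setattr__(self, "pos_mixture", _norm(self.pos_mixture))
        object.__setattr__(self, "pronoun_mixture", _norm(self.pronoun_mixture))
        object.__setattr__(self, "polarity_mixture", _norm(self.polarity_mixture))
        if len(self.hourly_weights) != 24 or len(self.weekday_weights) != 7:
            raise ValueError("need 24 hourly and 7 weekday weights")
        if len(self.pos_mixture) != len(POS_CATEGORIES):
            raise ValueError("pos_mixture must cover the 8 categories")
        if len(self.pronoun_mixture) != len(PRONOUN_PERSONS):
            raise ValueError("pronoun_mixture must cover the 6 persons")
        for r in list(self.emotion_rates.values()) + [self.negation_rate]:
            if r < 0:
                raise ValueError("rates must be >= 0")

    def scaled(self, total_tweets: int) -> "PopulationSpec":
        """Same rates, smaller cohort: aim for ~``total_tweets`` timeline
        tweets while keeping the users-to-tweets proportion of the preset."""
        factor = total_tweets / (self.n_users * self.tweets_per_user_mean)
        n_users = max(5, round(self.n_users * np.sqrt(factor)))
        mean = max(5.0, total_tweets / n_users)
        return replace(self, n_users=n_users, tweets_per_user_mean=mean)


def control_spec() -> PopulationSpec:
    """Control-population preset (general Twitter users)."""
    hourly = (
        # strong daytime activity, evening peak, quiet small hours
        0.55, 0.30, 0.18, 0.12, 0.10, 0.12,
        0.20, 0.45, 0.80, 1.00, 1.10, 1.15,
        1.10, 1.15, 1.20, 1.25, 1.30, 1.35,
        1.40, 1.50, 1.55, 1.45, 1.15, 0.80,
    )
    weekday = (1.0, 1.0, 1.0, 1.0, 1.0, 0.6, 0.6)  # weekend drop
    return PopulationSpec(
        name="control",
        n_users=450,
        tweets_per_user_mean=2536.0,
        tweets_per_user_dispersion=2.0,
        retweet_rate=0.3755,
        hourly_weights=hourly,
        weekday_weights=weekday,
        pos_mixture=(0.2848, 0.2058, 0.0955, 0.0735, 0.1323, 0.0616, 0.1059, 0.0406),
        pronoun_mixture=(0.3837, 0.07, 0.18, 0.02, 0.25, 0.0963),
        emotion_rates={
            "happiness": 0.2847,
            "sadness": 0.0940,
            "anger": 0.0481,
            "fear": 0.0427,
            "disgust": 0.0267,
            "surprise": 0.0380,
        },
        negation_rate=0.28,
        polarity_mixture=(0.1893, 0.1454, 0.2097, 0.4556),
        graded_negative_fraction=0.45,
        entity_rates={
            "link": 0.3532, "hashtag": 0.1313, "mention": 0.44, "emoji": 0.1361
        },
        length_mean=14.0,
        length_sd=6.0,
        utc_offset_seconds=7200,
        profile_templates=(
            "Amante del fútbol y de la buena música",
            "Fotógrafo aficionado y viajero",
            "Estudiante de historia en la universidad",
            "Padre de dos hijos y cocinero amateur",
            "Aquí para hablar de series y películas",
        ),
    )


def depressive_spec() -> PopulationSpec:
    """Depressive-population preset (self-declared in profile)."""
    hourly = (
        # flatter profile with a relatively heavier night share
        0.75, 0.65, 0.55, 0.50, 0.45, 0.45,
        0.50, 0.55, 0.60, 0.65, 0.70, 0.72,
        0.70, 0.72, 0.75, 0.78, 0.80, 0.82,
        0.85, 0.88, 0.92, 0.95, 0.90, 0.82,
    )
    weekday = (1.05, 1.0, 1.0, 1.0, 1.0, 1.02, 1.05)  # near-flat week
    return PopulationSpec(
        name="depressive",
        n_users=90,
        tweets_per_user_mean=2107.0,
        tweets_per_user_dispersion=2.0,
        retweet_rate=0.2569,
        hourly_weights=hourly,
        weekday_weights=weekday,
        pos_mixture=(0.1777, 0.2636, 0.1486, 0.0547, 0.1170, 0.0927, 0.0815, 0.0642),
        pronoun_mixture=(0.5759, 0.03, 0.12, 0.01, 0.19, 0.0741),
        emotion_rates={
            "happiness": 0.2876,
            "sadness": 0.1762,
            "anger": 0.0899,
            "fear": 0.0415,
            "disgust": 0.0553,
            "surprise": 0.0409,
        },
        negation_rate=0.49,
        polarity_mixture=(0.1906, 0.2225, 0.2932, 0.2937),
        graded_negative_fraction=0.62,
        entity_rates={
            "link": 0.1807, "hashtag": 0.0144, "mention": 0.0927, "emoji": 0.0572
        },
        length_mean=11.0,
        length_sd=5.5,
        utc_offset_seconds=7200,
        profile_templates=(
            "Paciente psiquiátrico con depresión crónica",
            "Luchando cada día contra la depre",
            "Diagnosticada de depresión hace dos años",
            "Vivo con depresión y ansiedad",
            "En tratamiento por depresión desde enero",
        ),
    )


# ---------------------------------------------------------------------------
# Generation


@dataclass
class TweetTruth:
    """Ground-truth bookkeeping for one generated tweet."""

    tweet_id: str
    is_retweet: bool
    pos_counts: dict[str, int] = field(default_factory=dict)
    filler_pos_counts: dict[str, int] = field(default_factory=dict)
    filler_person_counts: dict[str, int] = field(default_factory=dict)
    negations: int = 0
    emotions: dict[str, int] = field(default_factory=dict)
    polarity_cell: str = "none"
    keywords_injected: int = 0
    entities: dict[str, int] = field(default_factory=dict)
    local_hour: int = 0
    local_weekday: int = 0


def _user_rng(seed: int, pop_index: int, user_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(pop_index, user_index))
    )


def _random_suffix(rng: np.random.Generator, k: int = 8) -> str:
    alphabet = string.ascii_lowercase + string.digits
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=k))


def generate_user(
    spec: PopulationSpec,
    bank: VocabularyBank,
    user_index: int,
    seed: int = 0,
    pop_index: int = 0,
) -> tuple[UserProfile, list[Tweet], list[TweetTruth]]:
    """One user: a profile, a timeline, and per-tweet ground truth."""
    rng = _user_rng(seed, pop_index, user_index)
    user_id = f"{spec.name}-u{user_index}"
    profile = UserProfile(
        user_id, spec.profile_templates[user_index % len(spec.profile_templates)]
    )

    k = spec.tweets_per_user_dispersion
    p = k / (k + spec.tweets_per_user_mean)
    n_tweets = max(1, int(rng.negative_binomial(k, p)))

    day_weights = np.array(
        [spec.weekday_weights[(WINDOW_START + timedelta(days=d)).weekday()]
         for d in range(WINDOW_DAYS)]
    )
    day_weights /= day_weights.sum()
    hour_p = np.asarray(spec.hourly_weights)
    pos_p = np.asarray(spec.pos_mixture)
    person_p = np.asarray(spec.pronoun_mixture)
    pol_p = np.asarray(spec.polarity_mixture)
    emo_names = list(EMOTIONS)
    emo_rates = np.array([spec.emotion_rates.get(e, 0.0) for e in emo_names])
    ent_names = list(ENTITY_KINDS)
    ent_rates = np.array([spec.entity_rates.get(e, 0.0) for e in ent_names])

    days = rng.choice(WINDOW_DAYS, size=n_tweets, p=day_weights)
    hours = rng.choice(24, size=n_tweets, p=hour_p)
    minutes = rng.integers(0, 60, size=n_tweets)
    seconds = rng.integers(0, 60, size=n_tweets)
    is_rt = rng.random(n_tweets) < spec.retweet_rate
    lengths = np.maximum(
        1, np.rint(rng.normal(spec.length_mean, spec.length_sd, size=n_tweets))
    ).astype(int)

    tweets: list[Tweet] = []
    truths: list[TweetTruth] = []
    offset = timedelta(seconds=spec.utc_offset_seconds)
    for i in range(n_tweets):
        truth = TweetTruth(
            tweet_id=f"{user_id}-t{i}",
            is_retweet=bool(is_rt[i]),
            pos_counts={c: 0 for c in POS_CATEGORIES},
            filler_pos_counts={c: 0 for c in POS_CATEGORIES},
            filler_person_counts={pp: 0 for pp in PRONOUN_PERSONS},
            emotions={e: 0 for e in emo_names},
            entities={e: 0 for e in ent_names},
            local_hour=int(hours[i]),
            local_weekday=int((WINDOW_START + timedelta(days=int(days[i]))).weekday()),
        )
        words: list[str] = []

        cats = rng.choice(len(POS_CATEGORIES), size=lengths[i], p=pos_p)
        for ci in cats:
            cat = POS_CATEGORIES[ci]
            if cat == "pronoun":
                person = PRONOUN_PERSONS[rng.choice(len(PRONOUN_PERSONS), p=person_p)]
                word = bank.personal_pronouns[person][
                    rng.integers(len(bank.personal_pronouns[person]))
                ]
                truth.filler_person_counts[person] += 1
            else:
                pool = bank.neutral[cat]
                word = pool[rng.integers(len(pool))]
            words.append(word)
            truth.filler_pos_counts[cat] += 1

        n_neg = int(rng.poisson(spec.negation_rate))
        truth.negations = n_neg
        for _ in range(n_neg):
            words.append(bank.negation_words[rng.integers(len(bank.negation_words))])

        hits = rng.random(len(emo_names)) < emo_rates
        for e_idx in np.flatnonzero(hits):
            emo = emo_names[e_idx]
            pool = bank.emotion_pools[emo]
            words.append(pool[rng.integers(len(pool))])
            truth.emotions[emo] += 1

        cell = POLARITY_CELLS[rng.choice(len(POLARITY_CELLS), p=pol_p)]
        truth.polarity_cell = cell
        if cell == "positive":
            words.append(bank.binary_positive[rng.integers(len(bank.binary_positive))])
        elif cell == "negative":
            words.append(bank.binary_negative[rng.integers(len(bank.binary_negative))])
        elif cell == "graded":
            sign = -1 if rng.random() < spec.graded_negative_fraction else 1
            strength = "strong" if rng.random() < 0.5 else "moderate"
            pool = bank.graded_pools[(sign, strength)]
            words.append(pool[rng.integers(len(pool))])

        for w in words:
            pos = bank.word_pos.get(w)
            if pos in truth.pos_counts:
                truth.pos_counts[pos] += 1

        tokens = [words[j] for j in rng.permutation(len(words))]
        ent_hits = rng.random(len(ent_names)) < ent_rates
        for e_idx in np.flatnonzero(ent_hits):
            kind = ent_names[e_idx]
            truth.entities[kind] += 1
            if kind == "hashtag":
                tokens.append("#" + _HASHTAG_TOPICS[rng.integers(len(_HASHTAG_TOPICS))])
            elif kind == "link":
                tokens.append("https://t.co/" + _random_suffix(rng))
            elif kind == "mention":
                tokens.append(f"@usuario{rng.integers(1000)}")
            else:
                tokens.append(_EMOJI_SET[rng.integers(len(_EMOJI_SET))])
        text = " ".join(tokens)
        if is_rt[i]:
            text = f"RT @usuario{rng.integers(1000)}: {text}"

        local = WINDOW_START + timedelta(days=int(days[i])) + timedelta(
            hours=int(hours[i]), minutes=int(minutes[i]), seconds=int(seconds[i])
        )
        tweets.append(
            Tweet(
                tweet_id=truth.tweet_id,
                user_id=user_id,
                text=text,
                created_at_utc=local - offset,
                utc_offset_seconds=spec.utc_offset_seconds,
                is_retweet=bool(is_rt[i]),
                lang=spec.lang,
            )
        )
        truths.append(truth)
    return profile, tweets, truths


# ---------------------------------------------------------------------------
# Full study


@dataclass
class StudyData:
    control: Corpus
    depressive_users: Corpus
    depressive_tweets: Corpus
    truth: dict

    def corpora(self) -> dict[str, Corpus]:
        return {
            "control": self.control,
            "depressive_users": self.depressive_users,
            "depressive_tweets": self.depressive_tweets,
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for label, corpus in self.corpora().items():
            write_corpus(corpus, out / f"{label}.jsonl")
        (out / "truth.json").write_text(
            json.dumps(self.truth, ensure_ascii=False, indent=1, default=str),
            encoding="utf-8",
        )


def _aggregate(truths: list[TweetTruth]) -> dict:
    agg = {
        "n_tweets": len(truths),
        "pos_counts": {c: 0 for c in POS_CATEGORIES},
        "filler_pos_counts": {c: 0 for c in POS_CATEGORIES},
        "filler_person_counts": {p: 0 for p in PRONOUN_PERSONS},
        "negations": 0,
        "emotions": {e: 0 for e in EMOTIONS},
        "polarity_cells": {c: 0 for c in POLARITY_CELLS},
        "keywords_injected": 0,
        "entities": {e: 0 for e in ENTITY_KINDS},
    }
    for t in truths:
        for c in POS_CATEGORIES:
            agg["pos_counts"][c] += t.pos_counts[c]
            agg["filler_pos_counts"][c] += t.filler_pos_counts[c]
        for p in PRONOUN_PERSONS:
            agg["filler_person_counts"][p] += t.filler_person_counts[p]
        agg["negations"] += t.negations
        for e in EMOTIONS:
            agg["emotions"][e] += t.emotions[e]
        agg["polarity_cells"][t.polarity_cell] += 1
        agg["keywords_injected"] += t.keywords_injected
        for e in ENTITY_KINDS:
            agg["entities"][e] += t.entities[e]
    return agg


def generate_study(
    control: PopulationSpec | None = None,
    depressive: PopulationSpec | None = None,
    flagged_fraction: float = 0.0071,
    seed: int = 0,
    min_flagged_per_user: int = 10,
) -> StudyData:
    """Generate the three-corpus synthetic study plus a truth sidecar.

    Flagged tweets are sampled from each depressive user's non-retweet
    timeline (at least ``min_flagged_per_user`` per user when the timeline
    allows, mirroring the cohort retention rule) and receive one or two
    extra depression-keyword tokens before assembly.
    """
    if not 0.0 <= flagged_fraction <= 1.0:
        raise ValueError("flagged_fraction must be in [0, 1]")
    control = control or control_spec()
    depressive = depressive or depressive_spec()
    bank = build_vocabulary(seed)
    study_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(99,))
    )

    profiles: dict[str, UserProfile] = {}
    truths_by_id: dict[str, TweetTruth] = {}

    def population(spec: PopulationSpec, pop_index: int):
        timelines = {}
        for u in range(spec.n_users):
            prof, tweets, truths = generate_user(spec, bank, u, seed, pop_index)
            profiles[prof.user_id] = prof
            timelines[prof.user_id] = tweets
            for t in truths:
                truths_by_id[t.tweet_id] = t
        return timelines

    control_tl = population(control, 0)
    dep_tl = population(depressive, 1)

    # flag depressive tweets and inject screening keywords into them
    flagged_ids: list[str] = []
    if flagged_fraction > 0:
        for uid in sorted(dep_tl):
            candidates = [t for t in dep_tl[uid] if not t.is_retweet]
            if not candidates:
                continue
            n_flag = max(
                min(min_flagged_per_user, len(candidates)),
                round(flagged_fraction * len(candidates)),
            )
            idx = study_rng.choice(len(candidates), size=n_flag, replace=False)
            chosen = {candidates[i].tweet_id for i in idx}
            new_tl = []
            for t in dep_tl[uid]:
                if t.tweet_id in chosen:
                    n_kw = int(study_rng.integers(1, 3))
                    kws = [
                        bank.keyword_forms[study_rng.integers(len(bank.keyword_forms))]
                        for _ in range(n_kw)
                    ]
                    t = replace(t, text=t.text + " " + " ".join(kws))
                    truth = truths_by_id[t.tweet_id]
                    truth.keywords_injected += len(kws)
                    for w in kws:
                        pos = bank.word_pos.get(w)
                        if pos in truth.pos_counts:
                            truth.pos_counts[pos] += 1
                    flagged_ids.append(t.tweet_id)
                new_tl.append(t)
            dep_tl[uid] = new_tl

    ctrl_corpus, dep_users_corpus, dep_tweets_corpus = assemble_datasets(
        dep_tl, flagged_ids, control_tl, profiles
    )

    truth = {
        "seed": seed,
        "flagged_fraction": flagged_fraction,
        "specs": {"control": asdict(control), "depressive": asdict(depressive)},
        "flagged_ids": sorted(flagged_ids),
        "datasets": {
            label: _aggregate([truths_by_id[t.tweet_id] for t in corpus.tweets])
            for label, corpus in (
                ("control", ctrl_corpus),
                ("depressive_users", dep_users_corpus),
                ("depressive_tweets", dep_tweets_corpus),
            )
        },
    }
    return StudyData(ctrl_corpus, dep_users_corpus, dep_tweets_corpus, truth)


__all__ = [
    "WINDOW_START",
    "WINDOW_DAYS",
    "POLARITY_CELLS",
    "ENTITY_KINDS",
    "VocabularyBank",
    "PopulationSpec",
    "TweetTruth",
    "StudyData",
    "build_vocabulary",
    "control_spec",
    "depressive_spec",
    "generate_user",
    "generate_study",
]
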