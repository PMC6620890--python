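"""Study orchestration: features per dataset, comparison battery, CSV bundle.

``run_study`` drives the whole pipeline from one configuration: obtain the
three corpora (from JSONL files or the synthetic generator), extract the
linguistic and behavioral features of each, run the 22-test comparison
battery, and write the result tables as CSV.  Identical configuration and
corpora produce byte-identical outputs.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .corpus_io import Corpus, read_corpus
from .tokenizer import char_count, count_entities, tokenize_tweet
from .tagging import (
    POS_CATEGORIES,
    PRONOUN_PERSONS,
    DictionaryTagger,
    POSProfile,
    PronounProfile,
    Tagger,
    tag_tokens,
)
from .lexicons import (
    EMOTIONS,
    DEFAULT_T_MOD,
    NO_POLARITY,
    EmotionLexicon,
    NegationLexicon,
    PolarityLexicon,
    detect_negations,
    score_emotions,
    score_polarity_binary,
    score_polarity_graded,
)
from .temporal import TemporalProfile, hourly_profile, weekday_profile
from .stats import SummaryStats, run_comparisons
from . import _vocabulary as vocab
from . import synthetic

log = logging.getLogger("tuitvig")

ENTITY_KINDS = ("hashtag", "link", "mention", "emoji")

REPORT_FILES = (
    "table2.csv", "pronouns.csv", "emotions.csv", "negations.csv",
    "polarity.csv", "temporal.csv", "comparisons.csv", "entity_rates.csv",
    "topwords.csv",
)


@dataclass
class DatasetFeatures:
    """Single-pass aggregate features of one corpus."""

    label: str
    n_tweets: int
    pos: POSProfile
    pronouns: PronounProfile
    emotions: dict[str, int]
    negation_counts: np.ndarray  # per tweet
    binary_labels: list[str]
    graded_labels: list[str]
    char_counts: np.ndarray  # per tweet
    entity_tweets: dict[str, int]  # tweets containing >= 1 of each entity
    top_words: list[tuple[str, int]]
    hourly: TemporalProfile | None = None
    weekday: TemporalProfile | None = None

    @property
    def chars(self) -> SummaryStats:
        return SummaryStats.of(self.char_counts)

    def negation_prevalence(self) -> float:
        return float((self.negation_counts > 0).mean())

    def binary_label_counts(self) -> dict[str, int]:
        c = Counter(self.binary_labels)
        return {k: c[k] for k in ("positive", "negative") if c[k]}

    def graded_label_counts(self) -> dict[str, int]:
        c = Counter(self.graded_labels)
        order = ("positive", "moderate_positive", "moderate_negative", "negative")
        return {k: c[k] for k in order if c[k]}


def extract_features(
    corpus: Corpus,
    tagger: Tagger | None = None,
    negation_lexicon: NegationLexicon | None = None,
    emotion_lexicon: EmotionLexicon | None = None,
    binary_lexicon: PolarityLexicon | None = None,
    graded_lexicon: PolarityLexicon | None = None,
    stopwords: set[str] | None = None,
    t_mod: float = DEFAULT_T_MOD,
    tie_rule: str = NO_POLARITY,
    top_k: int = 200,
    with_temporal: bool = True,
) -> DatasetFeatures:
    """Tokenize + tag each tweet once and aggregate every tweet-level feature."""
    tagger = tagger or DictionaryTagger.bundled()
    negation_lexicon = negation_lexicon or NegationLexicon.bundled()
    emotion_lexicon = emotion_lexicon or EmotionLexicon.bundled()
    binary_lexicon = binary_lexicon or PolarityLexicon.bundled_binary()
    graded_lexicon = graded_lexicon or PolarityLexicon.bundled_graded()
    stopwords = stopwords if stopwords is not None else set(vocab.STOPWORDS)

    pos = POSProfile()
    pronouns = PronounProfile()
    emotions = {e: 0 for e in EMOTIONS}
    negs: list[int] = []
    binary: list[str] = []
    graded: list[str] = []
    chars: list[int] = []
    entity_tweets = {e: 0 for e in ENTITY_KINDS}
    word_counts: Counter[str] = Counter()

    for tweet in corpus.tweets:
        tokens = tokenize_tweet(tweet.text)
        for tt in tag_tokens(tokens, tagger):
            if tt.pos in pos.counts:
                pos.counts[tt.pos] += 1
            if tt.pronoun_person in pronouns.counts:
                pronouns.counts[tt.pronoun_person] += 1
        for emo, k in score_emotions(tokens, emotion_lexicon).items():
            emotions[emo] += k
        negs.append(detect_negations(tokens, negation_lexicon))
        binary.append(score_polarity_binary(tokens, binary_lexicon, tie_rule))
        graded.append(score_polarity_graded(tokens, graded_lexicon, t_mod))
        chars.append(char_count(tweet.text))
        ents = count_entities(tokens)
        for kind, n in (
            ("hashtag", ents.hashtags), ("link", ents.links),
            ("mention", ents.mentions), ("emoji", ents.emojis),
        ):
            if n > 0:
                entity_tweets[kind] += 1
        word_counts.update(
            t.normalized
            for t in tokens
            if t.kind == "word" and t.normalized not in stopwords
        )

    top = sorted(word_counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
    feats = DatasetFeatures(
        label=corpus.label,
        n_tweets=len(corpus),
        pos=pos,
        pronouns=pronouns,
        emotions=emotions,
        negation_counts=np.asarray(negs, dtype=int),
        binary_labels=binary,
        graded_labels=graded,
        char_counts=np.asarray(chars, dtype=int),
        entity_tweets=entity_tweets,
        top_words=top,
    )
    if with_temporal and len(corpus):
        try:
            feats.hourly = hourly_profile(corpus)
            feats.weekday = weekday_profile(corpus)
        except ValueError:
            log.warning("%s: no temporally valid tweets; skipping profiles", corpus.label)
    log.info("%s: features extracted over %d tweets", corpus.label, len(corpus))
    return feats


def comparisons_frame(features: Mapping[str, DatasetFeatures]) -> pd.DataFrame:
    """The 22-row comparison battery over the three datasets."""
    hourly = {
        lab: f.hourly.per_user
        for lab, f in features.items()
        if f.hourly is not None and lab in ("control", "depressive_users")
    }
    weekday = {
        lab: f.weekday.per_user
        for lab, f in features.items()
        if f.weekday is not None and lab in ("control", "depressive_users")
    }
    return run_comparisons(
        pos={lab: f.pos.counts for lab, f in features.items()},
        pronouns={lab: f.pronouns.counts for lab, f in features.items()},
        emotions={lab: f.emotions for lab, f in features.items()},
        polarity_binary={lab: f.binary_label_counts() for lab, f in features.items()},
        polarity_graded={lab: f.graded_label_counts() for lab, f in features.items()},
        chars={lab: f.chars for lab, f in features.items()},
        negations={lab: f.negation_counts for lab, f in features.items()},
        hourly=hourly,
        weekday=weekday,
    )


# ---------------------------------------------------------------------------
# Configuration + full run


@dataclass
class RunConfig:
    out_dir: Path
    corpora: dict[str, Path] = field(default_factory=dict)  # label -> JSONL
    synth_total_tweets: int = 10_000  # per population, when no corpora given
    flagged_fraction: float = 0.0071
    min_flagged: int = 10
    t_mod: float = DEFAULT_T_MOD
    tie_rule: str = NO_POLARITY
    top_k: int = 200
    seed: int = 0
    lexicon_paths: dict[str, Path] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        self.corpora = {k: Path(v) for k, v in self.corpora.items()}
        for label, p in self.corpora.items():
            if not p.exists():
                raise FileNotFoundError(f"{label} corpus not found: {p}")
        if not 0 < self.t_mod < 1:
            raise ValueError("t_mod must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**raw)


def load_corpora(config: RunConfig) -> dict[str, Corpus]:
    if config.corpora:
        return {
            label: read_corpus(path, label=label)
            for label, path in config.corpora.items()
        }
    specs = {
        "control": synthetic.control_spec(),
        "depressive": synthetic.depressive_spec(),
    }
    # target analyzed (post-retweet) tweets per population
    scaled = {
        name: spec.scaled(int(config.synth_total_tweets / (1 - spec.retweet_rate)))
        for name, spec in specs.items()
    }
    study = synthetic.generate_study(
        control=scaled["control"],
        depressive=scaled["depressive"],
        flagged_fraction=config.flagged_fraction,
        seed=config.seed,
        min_flagged_per_user=config.min_flagged,
    )
    return study.corpora()


def run_study(config: RunConfig) -> dict[str, DatasetFeatures]:
    """Full pipeline: corpora -> features -> comparisons -> CSV bundle."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    corpora = load_corpora(config)

    lex = config.lexicon_paths
    features = {
        label: extract_features(
            corpus,
            negation_lexicon=(
                NegationLexicon.from_file(lex["negations"]) if "negations" in lex else None
            ),
            emotion_lexicon=(
                EmotionLexicon.from_file(lex["emotions"]) if "emotions" in lex else None
            ),
            binary_lexicon=(
                PolarityLexicon.from_file(lex["polarity_binary"], "binary")
                if "polarity_binary" in lex else None
            ),
            graded_lexicon=(
                PolarityLexicon.from_file(lex["polarity_graded"], "graded")
                if "polarity_graded" in lex else None
            ),
            t_mod=config.t_mod,
            tie_rule=config.tie_rule,
            top_k=config.top_k,
        )
        for label, corpus in corpora.items()
    }

    frames: dict[str, pd.DataFrame] = {}
    frames["table2.csv"] = pd.DataFrame(
        [
            {
                "dataset": lab,
                "category": cat,
                "count": f.pos.counts[cat],
                "pct": round(f.pos.percentages()[cat], 2),
            }
            for lab, f in features.items()
            for cat in POS_CATEGORIES
        ]
    )
    frames["pronouns.csv"] = pd.DataFrame(
        [
            {
                "dataset": lab,
                "person": person,
                "count": f.pronouns.counts[person],
                "pct": round(f.pronouns.percentages()[person], 2),
            }
            for lab, f in features.items()
            for person in PRONOUN_PERSONS
        ]
    )
    frames["emotions.csv"] = pd.DataFrame(
        [
            {
                "dataset": lab,
                "emotion": emo,
                "count": f.emotions[emo],
                "pct": round(
                    100.0 * f.emotions[emo] / max(1, sum(f.emotions.values())), 2
                ),
            }
            for lab, f in features.items()
            for emo in EMOTIONS
        ]
    )
    frames["negations.csv"] = pd.DataFrame(
        [
            {
                "dataset": lab,
                "negations_per_tweet": int(k),
                "n_tweets": int(n),
                "mean": round(float(f.negation_counts.mean()), 4),
                "prevalence_pct": round(100.0 * f.negation_prevalence(), 2),
            }
            for lab, f in features.items()
            for k, n in zip(*np.unique(f.negation_counts, return_counts=True))
        ]
    )
    frames["polarity.csv"] = pd.DataFrame(
        [
            {"dataset": lab, "scheme": scheme, "label": label_, "count": n}
            for lab, f in features.items()
            for scheme, labels in (("binary", f.binary_labels), ("graded", f.graded_labels))
            for label_, n in sorted(Counter(labels).items())
        ]
    )
    temporal_rows = []
    for lab, f in features.items():
        for kind, prof in (("hour", f.hourly), ("weekday", f.weekday)):
            if prof is None:
                continue
            for i, b in enumerate(prof.bins):
                temporal_rows.append(
                    {
                        "bin_type": kind,
                        "bin": b,
                        "dataset": lab,
                        "mean": prof.mean[i],
                        "sem": prof.sem[i],
                    }
                )
    frames["temporal.csv"] = pd.DataFrame(temporal_rows)
    frames["comparisons.csv"] = comparisons_frame(features)
    frames["entity_rates.csv"] = pd.DataFrame(
        [
            {
                "dataset": lab,
                "entity": kind,
                "tweets_with": f.entity_tweets[kind],
                "n_tweets": f.n_tweets,
                "pct": round(100.0 * f.entity_tweets[kind] / max(1, f.n_tweets), 2),
            }
            for lab, f in features.items()
            for kind in ENTITY_KINDS
        ]
    )
    frames["topwords.csv"] = pd.DataFrame(
        [
            {"dataset": lab, "rank": i + 1, "word": w, "count": n}
            for lab, f in features.items()
            for i, (w, n) in enumerate(f.top_words)
        ]
    )
    frames["characters.csv"] = pd.DataFrame(
        [
            {
                "dataset": lab,
                "mean": round(f.chars.mean, 2),
                "sd": round(f.chars.sd, 2),
                "n": f.chars.n,
            }
            for lab, f in features.items()
        ]
    )
    for name, frame in frames.items():
        frame.to_csv(out / name, index=False)
        log.info("wrote %s (%d rows)", name, len(frame))
    return features


__all__ = [
    "REPORT_FILES",
    "DatasetFeatures",
    "RunConfig",
    "extract_features",
    "comparisons_frame",
    "load_corpora",
    "run_study",
]
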