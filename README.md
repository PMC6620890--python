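# tuitvig

Behavioral and linguistic screening of Spanish-language tweet corpora for
signs of depression.

Depression changes how people write and when they post. On Twitter this
shows up as measurable contrasts between the general population and users
who state in their profile that they live with depression: depressed users
post less overall but relatively more at night, their weekly activity stays
flat where the general population drops off at the weekend, they use fewer
nouns and more verbs, pronouns and adverbs, far more first-person-singular
pronouns, more sadness/anger/disgust vocabulary, more negation cues
(*no, nada, nadie, nunca* …), and more negatively polarized words.
`tuitvig` packages that analysis as a tested, reusable pipeline for
infoveillance work: dataset screening, tweet-level linguistic features,
timezone-adjusted activity profiles and the statistical comparison battery
between three corpora — a **control** population, a **depressive-user**
population, and a hand-flagged **depressive-tweet** subset.

Because real tweet corpora cannot be redistributed, the package ships a
synthetic-corpus generator with exact ground truth: token-sequence tweets
drawn from a closed vocabulary aligned with the bundled tagger and
lexicons, with every generating rate (POS mixture, pronoun persons, emotion
/ negation / polarity rates, diurnal and weekly activity, tweet length)
bookkept per tweet, so every pipeline stage is validated hermetically.

## What it computes

* **Screening** — profile matching against the closed set of *depr-*
  derivations (`depre, depresión, depresivo/a, deprimido/a`, plus the
  unaccented `depresion`), the ≥10-flagged-tweets retention rule, seeded
  control sampling, and assembly of the three pairwise-disjoint datasets.
* **Tokenization** — a rule-based Twitter tokenizer (mentions, hashtags,
  URLs, emoji with ZWJ-sequence merging, words, numbers, punctuation),
  character counts, entity prevalence, top-k word ranking.
* **Tagging** — eight-way POS profiling (noun, verb, pronoun, adjective,
  determiner, adverb, adposition, conjunction) and pronoun person/number
  classification (1S/1P/2S/2P/3S/3P) through a pluggable tagging contract
  with a deterministic dictionary fallback.
* **Lexicon scoring** — negation-cue counts; six basic emotions
  (happiness, sadness, anger, fear, disgust, surprise); binary polarity by
  hit majority; graded polarity by mean matched value in [−1, 1] against a
  moderate/strong threshold `t_mod` (default 0.5).
* **Temporal profiles** — per-user mean tweets per hour-of-day and weekday
  bin (normalized by observed local days, timezone-adjusted), group mean ±
  SEM.
* **Statistics** — Pearson χ² on contingency tables, Welch's *t* (from raw
  samples or printed mean/SD/n summaries), Mann-Whitney *U* with midrank
  ties (exact null for small tie-free samples), and split-plot
  repeated-measures ANOVA with the Greenhouse-Geisser correction
  ε̂ = (Σλ)² / ((L−1)Σλ²) over the eigenvalues of the double-centered
  pooled within-group covariance. The full battery is 22 comparisons.

## Worked example

The published summary tables for this kind of study are themselves inputs:
the statistical layer re-derives the reported test statistics from them.

```python
from tuitvig import reference
from tuitvig.stats import chi_square, welch_t

res = chi_square(reference.pos_table("control", "depressive_tweets"))
print(f"chi2 = {res.statistic:.1f}, df = {res.df:.0f}")
# chi2 = 2105.7, df = 7      (POS distribution, control vs depressive tweets)

t = welch_t(reference.CHAR_SUMMARY["control"],
            reference.CHAR_SUMMARY["depressive_users"])
print(f"t = {t.statistic:.1f}, df = {t.df:.1f}")
# t = 161.6, df = 213603.4   (characters per tweet, control vs depressive users)
```

The χ² of 2105.7 on 7 degrees of freedom says the eight-way POS
distribution of flagged depressive tweets differs overwhelmingly from the
control corpus; the Welch *t* of 161.6 reflects control tweets being ~18
characters longer on average at very large n. Tokenization is a one-liner:

```python
from tuitvig import tokenize_tweet
[(t.surface, t.kind) for t in tokenize_tweet("Hola @ana #feliz 😢 http://t.co/x")]
# [('Hola', 'word'), ('@ana', 'mention'), ('#feliz', 'hashtag'),
#  ('😢', 'emoji'), ('http://t.co/x', 'url')]
```

A full synthetic study from the shell:

```bash
tuitvig synth --out corpora/ --tweets 10000 --seed 1   # 3 JSONL corpora + truth.json
tuitvig run   --out report/  --tweets 10000 --seed 1   # CSV report bundle
```

`report/` then contains `table2.csv` (POS counts and percentages),
`pronouns.csv`, `emotions.csv`, `negations.csv`, `polarity.csv`,
`temporal.csv`, `entity_rates.csv`, `topwords.csv`, `characters.csv` and
`comparisons.csv` — the 22-row battery with statistic, degrees of freedom,
Greenhouse-Geisser ε where applicable, and raw plus Bonferroni-adjusted
p-values.

## Layout

| Module | Role |
| --- | --- |
| `tuitvig.corpus_io` | JSONL tweet corpora, record types, retweet/language filters |
| `tuitvig.screening` | keyword + profile matching, cohort retention, dataset assembly |
| `tuitvig.tokenizer` | Twitter-aware tokenization and surface counts |
| `tuitvig.tagging` | POS and pronoun-person profiling (dictionary tagger) |
| `tuitvig.lexicons` | negation, emotion and dual polarity scoring |
| `tuitvig.temporal` | timezone-adjusted hourly/weekday activity profiles |
| `tuitvig.stats` | χ², Welch t, Mann-Whitney U, GG mixed ANOVA, 22-test battery |
| `tuitvig.synthetic` | two-population generator with exact ground truth |
| `tuitvig.report` / `tuitvig.cli` | orchestration, CSV bundle, `tuitvig` CLI |

See `docs/methods.md` for the modelling choices, generator assumptions and
known limitations.
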