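# Methods

This note documents the models, rules and numerical choices behind
`tuitvig`, the assumptions they make, and what the synthetic validation
does and does not establish about real data.

## Study design being modelled

The pipeline reproduces a three-dataset observational design for
depression infoveillance on Spanish-language Twitter:

* **depressive users** — full timelines (capped at ~3200 tweets per user,
  retweets removed) of users whose profile description mentions a
  *depr-* derivation and who have at least 10 hand-flagged depressive
  tweets;
* **depressive tweets** — exactly those flagged tweets, removed from the
  previous dataset so the two are disjoint;
* **control** — timelines of randomly sampled users whose profiles do not
  mention depression, retweets removed.

Screening is deliberately mechanical. Profile matching is token-level,
case-insensitive and accent-sensitive against a closed derivation set
(`depre, depresión, depresivo, depresiva, deprimido, deprimida`); the one
relaxation is that the unaccented spelling `depresion` also matches, since
that accent is the one users routinely drop. The clinical judgment that
vetted profile statements (excluding quotes, jokes and irony) is not
automated: it enters as an externally supplied per-user boolean, which the
synthetic generator sets from ground truth. A retweet is anything carrying
the retweet metadata flag *or* a leading `RT @` marker — applying both is
conservative since collectors differ in which they preserve.

## Linguistic features

**Tokenization** is rule-based and total: URL, mention, hashtag, emoji,
word, number, punctuation, in that precedence; concatenating surfaces
reconstructs the tweet up to whitespace. Emoji are recognised by explicit
Unicode ranges with variation selectors, skin-tone modifiers, flag pairs
and ZWJ sequences merged into single tokens. Character counts are raw code
points of the tweet including URLs and mentions (no exclusion rule is part
of the reported convention; a variant that strips them is provided).

**Tagging** goes through a minimal contract — any callable mapping a word
form to a `(category, pronoun person)` pair — because a heavyweight
morphological tagger is an external tool, not part of this analysis. The
bundled tagger is an exact dictionary over a closed tagged vocabulary
(~620 forms); unknown words tag as `other`, and `other` is excluded from
the eight-way totals percentages are computed over. Clitic mapping for
pronoun persons: `se` → 3S, `nos` → 1P, `os` → 2P; `usted`/`ustedes` are
grouped with second person; indefinites (`nada`, `nadie`, …) count as
pronouns for POS purposes but carry no person and so never enter the
six-class person totals.

**Lexicon scoring.** Negations are counted, not scope-resolved: the
analysis reports how often negation cues occur, not whether they flip
polarity. Emotion terms may carry several emotions; each is incremented.
Tweet-level polarity aggregation is not dictated by the reported category
sets, so two simple deterministic rules are used: *binary* — hit majority
with ties defaulting to `none` (configurable); *graded* — the mean of
matched values, labelled `positive` at ≥ `t_mod`, `moderate_positive` in
(0, `t_mod`), symmetrically for negatives, `none` at 0 or no match.
`t_mod` defaults to 0.5, the midpoint between the bundled moderate (±0.4)
and strong (±0.8) term values.

The bundled lexicons are **synthetic stand-ins**, not redistributions of
published Spanish resources (licensing is unclear and tests must be
hermetic): ~150 binary-signed forms, ~90 graded forms and ~100 emotion
forms built by systematic gender/number expansion of hand-written stems.
Unlike real sentiment lexicons, the emotion, binary and graded term sets
are pairwise disjoint — this makes every lexicon hit attributable to
exactly one generator injection, which is what lets recovery tests assert
exact bookkeeping. Loaders accept externally supplied TSV resources with
the same layout for work on real corpora.

## Temporal profiles

Tweet times are stored in UTC and shifted by the user's declared UTC
offset; tweets without an offset are dropped from temporal analyses
(logged). Activity is normalized per user — mean tweets per bin per
distinct observed local day — before group means and SEMs are taken across
users, so heavy posters do not dominate. Weeks start Monday. Retweets are
excluded by default for consistency with the rest of the pipeline, with a
flag to include them.

## Statistics

* **χ²**: Pearson, uncorrected (no continuity correction), expected counts
  from row/column margins; all-zero columns are dropped before testing
  when families (e.g. emotions) can be absent from a small corpus.
* **Welch t**: computable from printed summaries (mean, SD, n) or raw
  samples; the two paths agree to machine precision by construction.
* **Mann-Whitney U**: midrank ties; exact null distribution (standard
  counting recurrence) when `n_x·n_y ≤ 400` and the data are tie-free,
  otherwise a normal approximation with tie-corrected variance and a
  continuity correction.
* **Mixed ANOVA**: split-plot decomposition (between-group, within-level,
  group×level interaction). Greenhouse-Geisser
  ε̂ = (Σλ)² / ((L−1) Σλ²) over the eigenvalues of the double-centered
  *pooled within-group* covariance, clamped to [1/(L−1), 1]; within and
  interaction F are tested on (ε̂·df₁, ε̂·df₂). F statistics agree with
  pingouin's `mixed_anova` to machine precision; ε̂ can differ slightly
  from implementations that pool across groups before centering. The
  group×level interaction is reported as the headline temporal effect
  since a bare "the distributions differ" claim is ambiguous between the
  three effects.
* **Battery**: 22 comparisons — χ² on POS, pronoun-person, emotion,
  binary-polarity and graded-polarity distributions for the three dataset
  pairs (15), Welch t on characters for control↔depressive-users and
  depressive-users↔depressive-tweets (2), Mann-Whitney on per-tweet
  negation counts for all three pairs (3), GG mixed ANOVA on the hourly
  and weekday per-user profiles for control↔depressive-users (2). No
  multiple-testing adjustment is applied to the primary p-values,
  mirroring the original analysis; a Bonferroni column is emitted for
  transparency.

Polarity prevalence uses tweet counts as the denominator. Published
prevalence figures of this kind sometimes carry denominators exceeding the
tweet count (their basis is not stated); this implementation does not
imitate that.

## Synthetic generator

Tweets are token sequences, not grammatical Spanish: the analysis operates
entirely on token and lexicon statistics, so grammaticality is irrelevant,
and exact recovery testing requires that every emitted word be resolvable
by the tagger and attributable to one measured rate. Per tweet: a
truncated-normal filler length (≥1) drawn from the population's POS
mixture (pronoun fillers additionally draw a person from the
person mixture), plus independent injections — Poisson negation cues,
per-emotion Bernoulli emotion words, one polarity draw over
{binary-positive, binary-negative, graded, none} (graded words signed by a
population-specific negative fraction, strong/moderate 50/50), and
Bernoulli hashtag/link/mention/emoji entities. Timestamps come from
weekday×hour weight products over a 180-day window starting on a Monday,
in local time, converted to UTC via the population's offset (+0200,
a Spanish summer offset). Flagged tweets are sampled per depressive user
(at least 10 each, echoing the retention rule) and receive one or two
extra depression-keyword tokens. Every user has an independent RNG
substream derived from (seed, population, user index), so corpora are
byte-reproducible and insensitive to generation order.

Population presets encode the reported control-vs-depressive contrasts:
POS mixtures (noun 28.48% vs 17.77%, verb 20.58% vs 26.36%, …), 1S pronoun
shares 38.37% vs 57.59%, negation means 0.28 vs 0.49, binary polarity
prevalences 33.47% vs 41.31% with negative shares 43.46% vs 53.86%, graded
prevalences 20.97% vs 29.32%, entity prevalences, night-shifted hourly
weights and a ×0.6 weekend dip for controls versus a flat depressive week,
and shorter depressive tweets (filler length 11±5.5 vs 14±6 tokens,
chosen to land near the reported 66 vs 83 characters per tweet). Emotion
rates allocate the reported per-tweet emotion-word totals (0.53 vs 0.69)
across the six emotions using the reported happiness/sadness shares and
plausible splits of the remainder that preserve the reported directions
(more anger and disgust, less surprise share among depressive users).
Pronoun-person and emotion entries not individually reported were fixed
once at plausible values and not revisited. Cohort-shape defaults mirror
the original design (450 control / 90 depressive users, negative-binomial
timelines with dispersion 2, retweet rates 37.6% / 25.7%); `scaled()`
shrinks a preset toward a target corpus size preserving all rates, and the
validation suite runs at 10,000 analyzed tweets per population (recovery,
three seeds) and 20,000 per group (directional reproduction) — sizes at
which every 3-SE recovery band is a fraction of a percentage point.

**What passing tests show — and don't.** Recovery and direction tests
establish that the pipeline measures exactly what was injected and that
the comparison battery detects the encoded contrasts with the right signs.
They do not establish performance on real Spanish text: real corpora bring
tagger error, lexicon overlap and coverage gaps, code-switching,
orthographic noise, sarcasm and topic confounds that token-sequence
corpora deliberately exclude.

## Numerical and degenerate-input choices

* `top_words` ties break lexicographically; rankings are reproducible.
* Contingency tables reject empty/degenerate shapes and zero margins;
  prevalence over an empty label set returns (0, {}).
* Timeline truncation demands most-recent-first input and errors otherwise
  (an unsorted timeline signals a caller bug, not data noise).
* Corpus reading skips and counts malformed JSONL lines but aborts when
  more than half of a file fails to parse (wrong schema); duplicate tweet
  ids keep the first occurrence.
* Recovery criterion for the hourly mode: the measured modal bin's
  generating share must lie within 3 SE of the maximum generating share —
  for a deliberately near-flat profile several hours are statistically
  tied at the top, and demanding the literal argmax would reject correct
  behaviour.

## Known limitations

* The dictionary tagger has no morphological generalization; coverage
  outside the bundled vocabulary tags as `other`. For real corpora a
  statistical tagger should be plugged into the tagging contract.
* Negation is counted, never scope-resolved; polarity ignores negation,
  intensifiers and word-sense ambiguity.
* The graded polarity aggregation (mean of matched values) is one of
  several defensible rules; results near the `t_mod` boundary are
  sensitive to it.
* Emoji detection is range-based against the major emoji blocks, not a
  full Unicode emoji-data table; exotic sequences may split.
* Seasonality, user networks and longitudinal change are out of scope.
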