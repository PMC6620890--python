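"""Published summary counts from the motivating observational study.

A depression-infoveillance study of Spanish-language Twitter reported
dataset-level summary tables (the raw tweets are not redistributable).
Those printed summaries are themselves analysable inputs: the POS frequency
table, pronoun totals, negation prevalences and character-count summaries
below let the statistical layer re-derive the study's recomputable test
statistics without any raw data.

Counts are stored exactly as printed; derived quantities (percentages, test
statistics) are always recomputed by the package, never stored.
"""

from __future__ import annotations

from .stats import ContingencyTable, SummaryStats

#: POS frequencies per dataset (word tokens over eight categories).
POS_COUNTS: dict[str, dict[str, int]] = {
    "control": {
        "noun": 2_298_544,
        "verb": 1_660_700,
        "pronoun": 770_955,
        "adjective": 593_327,
        "determiner": 1_068_130,
        "adverb": 496_988,
        "adposition": 854_573,
        "conjunction": 327_852,
    },
    "depressive_users": {
        "noun": 270_104,
        "verb": 400_755,
        "pronoun": 225_913,
        "adjective": 83_089,
        "determiner": 177_795,
        "adverb": 140_963,
        "adposition": 123_867,
        "conjunction": 97_541,
    },
    "depressive_tweets": {
        "noun": 1_776,
        "verb": 3_391,
        "pronoun": 1_627,
        "adjective": 588,
        "determiner": 1_342,
        "adverb": 1_351,
        "adposition": 1_052,
        "conjunction": 659,
    },
}

#: Personal pronouns: (first-person-singular count, six-class total).
PRONOUN_1S: dict[str, tuple[int, int]] = {
    "control": (152_013, 396_181),
    "depressive_users": (71_768, 124_614),
    "depressive_tweets": (692, 865),
}

#: Tweets containing >= 1 negation cue: (count, tweets).
NEGATION_PREVALENCE: dict[str, tuple[int, int]] = {
    "control": (154_953, 712_588),
    "depressive_users": (48_137, 140_946),
    "depressive_tweets": (455, 1_000),
}

#: Per-tweet negation-cue count summaries (mean, SD).
NEGATION_SUMMARY: dict[str, tuple[float, float]] = {
    "control": (0.28, 0.59),
    "depressive_users": (0.49, 0.82),
    "depressive_tweets": (0.67, 0.91),
}

#: Characters per tweet (mean, SD, n).
CHAR_SUMMARY: dict[str, SummaryStats] = {
    "control": SummaryStats(83.48, 40.57, 712_589),
    "depressive_users": SummaryStats(65.76, 36.99, 140_946),
    "depressive_tweets": SummaryStats(67.51, 38.28, 1_000),
}


def pos_table(dataset_a: str, dataset_b: str) -> ContingencyTable:
    """Two-dataset POS contingency table from the printed counts."""
    return ContingencyTable.from_counts(
        {dataset_a: POS_COUNTS[dataset_a], dataset_b: POS_COUNTS[dataset_b]}
    )


__all__ = [
    "POS_COUNTS",
    "PRONOUN_1S",
    "NEGATION_PREVALENCE",
    "NEGATION_SUMMARY",
    "CHAR_SUMMARY",
    "pos_table",
]
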