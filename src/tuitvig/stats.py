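"""Statistical comparison layer.

Implements the four test families the dataset comparisons use:

* Pearson chi-square on contingency tables (no continuity correction);
* Welch's unequal-variance t test, computable from raw samples or from
  printed summaries (mean, SD, n) — the two paths agree exactly;
* Mann-Whitney U with midrank ties: exact null distribution for small
  samples without ties, otherwise a normal approximation with tie-corrected
  variance;
* split-plot (mixed) repeated-measures ANOVA with the Greenhouse-Geisser
  sphericity correction, ε̂ = (Σλ)² / ((L−1)Σλ²) over the eigenvalues of
  the double-centered pooled within-group covariance.

Only distribution tails come from scipy; the statistics themselves are
computed here so they can be checked against independent brute-force
oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

DATASET_PAIRS = (
    ("control", "depressive_users"),
    ("control", "depressive_tweets"),
    ("depressive_users", "depressive_tweets"),
)

EXACT_MWU_LIMIT = 400  # exact enumeration when n_x * n_y <= this and no ties


@dataclass(frozen=True)
class StatResult:
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    epsilon: float | None = None  # Greenhouse-Geisser, where applicable

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"invalid p-value {self.p_value}")


@dataclass(frozen=True)
class SummaryStats:
    """Printed-summary form of a sample: mean, SD and size."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2 for variance-based tests")

    @classmethod
    def of(cls, sample: Sequence[float]) -> "SummaryStats":
        arr = np.asarray(sample, dtype=float)
        return cls(float(arr.mean()), float(arr.std(ddof=1)), int(arr.size))


@dataclass(frozen=True)
class ContingencyTable:
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("contingency table needs >= 2 rows and columns")
        if (counts < 0).any():
            raise ValueError("negative counts")

    @classmethod
    def from_counts(
        cls, rows: Mapping[str, Mapping[str, float]], drop_zero_columns: bool = False
    ) -> "ContingencyTable":
        """Build from {row label: {column label: count}} dictionaries."""
        row_labels = tuple(rows)
        col_labels: tuple[str, ...] = tuple(
            dict.fromkeys(c for r in rows.values() for c in r)
        )
        counts = np.array(
            [[rows[r].get(c, 0) for c in col_labels] for r in row_labels], dtype=float
        )
        if drop_zero_columns:
            keep = counts.sum(axis=0) > 0
            counts = counts[:, keep]
            col_labels = tuple(c for c, k in zip(col_labels, keep) if k)
        return cls(row_labels, col_labels, counts)


def chi_square(table: ContingencyTable) -> StatResult:
    """Pearson chi-square of independence from row/column margins."""
    obs = table.counts
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero margin in contingency table")
    expected = row @ col / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return StatResult(stat, float(df), float(sps.chi2.sf(stat, df)))


def welch_t(a: SummaryStats, b: SummaryStats) -> StatResult:
    """Welch's t with Welch–Satterthwaite df, two-sided p."""
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    if va + vb == 0:
        raise ValueError("zero pooled variance")
    t = (a.mean - b.mean) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return StatResult(float(t), float(df), p)


def welch_t_raw(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Raw-sample path; identical to the summary path by construction."""
    return welch_t(SummaryStats.of(x), SummaryStats.of(y))


def _mwu_exact_sf(u: float, nx: int, ny: int) -> float:
    """Two-sided exact p for U under the no-ties null, by enumeration.

    Uses the standard recurrence A(k; m, n) = A(k−n; m−1, n) + A(k; m, n−1)
    for the number of rank arrangements with U = k, then doubles the
    smaller symmetric tail.
    """
    max_u = nx * ny
    # F[m, k]: arrangements with U = k for sample sizes (m, current n)
    F = np.zeros((nx + 1, max_u + 1))
    F[:, 0] = 1.0  # n = 0 base case
    for n in range(1, ny + 1):
        for m in range(1, nx + 1):
            # F[m-1] already updated for this n; F[m] still holds n-1 values
            F[m, n:] += F[m - 1, :-n]
    pmf = F[nx] / comb(nx + ny, nx)
    lo = min(u, max_u - u)
    p = 2.0 * float(pmf[: int(np.floor(lo)) + 1].sum())
    return min(1.0, p)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Mann-Whitney U for ``x`` with midrank ties, two-sided p.

    Exact enumeration when the samples are small (nx·ny ≤ 400) and tie-free;
    otherwise a normal approximation with tie-corrected variance and a
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    rx = ranks[:nx].sum()
    u = rx - nx * (nx + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = (tie_counts > 1).any()
    n = nx + ny
    if not has_ties and nx * ny <= EXACT_MWU_LIMIT:
        p = _mwu_exact_sf(u, nx, ny)
    else:
        mu = nx * ny / 2.0
        tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
        sigma2 = nx * ny / 12.0 * (n + 1 - tie_term)
        if sigma2 == 0:  # all values identical
            return StatResult(float(u), float(nx * ny), 1.0)
        z = (abs(u - mu) - 0.5) / np.sqrt(sigma2)
        z = max(z, 0.0)
        p = 2.0 * float(sps.norm.sf(z))
    return StatResult(float(u), float(nx * ny), min(1.0, p))


def gg_epsilon(data: np.ndarray, groups: Sequence) -> float:
    """Greenhouse-Geisser ε̂ from the pooled within-group covariance."""
    data = np.asarray(data, dtype=float)
    groups = np.asarray(groups)
    n, L = data.shape
    labels = list(dict.fromkeys(groups.tolist()))
    g = len(labels)
    pooled = np.zeros((L, L))
    for lab in labels:
        block = data[groups == lab]
        pooled += (block.shape[0] - 1) * np.cov(block, rowvar=False)
    pooled /= n - g
    C = np.eye(L) - np.ones((L, L)) / L
    M = C @ pooled @ C
    lam = np.linalg.eigvalsh(M)
    lam = np.clip(lam, 0, None)
    denom = (L - 1) * (lam**2).sum()
    if denom == 0:
        return 1.0
    eps = lam.sum() ** 2 / denom
    return float(min(1.0, max(eps, 1.0 / (L - 1))))


def mixed_anova_gg(data: np.ndarray, groups: Sequence) -> dict[str, StatResult]:
    """Split-plot ANOVA: between-group, within-level and interaction effects.

    ``data`` is subjects × levels (complete vectors); ``groups`` labels each
    subject.  The within and interaction F tests carry Greenhouse-Geisser
    corrected degrees of freedom.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be subjects x levels")
    if np.isnan(data).any():
        raise ValueError("incomplete subject vectors")
    groups = np.asarray(groups)
    n, L = data.shape
    if L < 2:
        raise ValueError("need >= 2 within-subject levels")
    labels = list(dict.fromkeys(groups.tolist()))
    g = len(labels)
    sizes = {lab: int((groups == lab).sum()) for lab in labels}
    if min(sizes.values()) < 2:
        raise ValueError("need >= 2 subjects per group")

    grand = data.mean()
    subj_means = data.mean(axis=1)
    level_means = data.mean(axis=0)
    ss_total = ((data - grand) ** 2).sum()
    ss_between_subj = L * ((subj_means - grand) ** 2).sum()
    ss_group = L * sum(
        sizes[lab] * (data[groups == lab].mean() - grand) ** 2 for lab in labels
    )
    ss_subj_within = ss_between_subj - ss_group
    ss_level = n * ((level_means - grand) ** 2).sum()
    ss_cells = sum(
        sizes[lab] * ((data[groups == lab].mean(axis=0) - grand) ** 2).sum()
        for lab in labels
    )
    ss_inter = ss_cells - ss_group - ss_level
    ss_error = ss_total - ss_between_subj - ss_level - ss_inter

    df_group, df_subj = g - 1, n - g
    df_level = L - 1
    df_inter = (g - 1) * (L - 1)
    df_error = (L - 1) * (n - g)

    eps = gg_epsilon(data, groups)

    ms_group = ss_group / df_group
    ms_subj = ss_subj_within / df_subj
    f_group = ms_group / ms_subj
    res_group = StatResult(
        float(f_group),
        (float(df_group), float(df_subj)),
        float(sps.f.sf(f_group, df_group, df_subj)),
    )

    ms_error = ss_error / df_error
    f_level = (ss_level / df_level) / ms_error
    res_level = StatResult(
        float(f_level),
        (eps * df_level, eps * df_error),
        float(sps.f.sf(f_level, eps * df_level, eps * df_error)),
        epsilon=eps,
    )
    f_inter = (ss_inter / df_inter) / ms_error
    res_inter = StatResult(
        float(f_inter),
        (eps * df_inter, eps * df_error),
        float(sps.f.sf(f_inter, eps * df_inter, eps * df_error)),
        epsilon=eps,
    )
    return {"group": res_group, "level": res_level, "interaction": res_inter}


# ---------------------------------------------------------------------------
# The full comparison battery


def _pair_chi2(
    family: str,
    counts: Mapping[str, Mapping[str, float]],
    rows: list,
) -> None:
    for a, b in DATASET_PAIRS:
        if a not in counts or b not in counts:
            raise ValueError(f"missing {family} profile for {a!r} or {b!r}")
        table = ContingencyTable.from_counts(
            {a: counts[a], b: counts[b]}, drop_zero_columns=True
        )
        res = chi_square(table)
        rows.append((f"{a} vs {b}", family, "chi_square", res))


def run_comparisons(
    pos: Mapping[str, Mapping[str, float]],
    pronouns: Mapping[str, Mapping[str, float]],
    emotions: Mapping[str, Mapping[str, float]],
    polarity_binary: Mapping[str, Mapping[str, float]],
    polarity_graded: Mapping[str, Mapping[str, float]],
    chars: Mapping[str, SummaryStats],
    negations: Mapping[str, Sequence[int]],
    hourly: Mapping[str, np.ndarray],
    weekday: Mapping[str, np.ndarray],
) -> pd.DataFrame:
    """Run the full battery over the three datasets.

    22 comparisons: chi-square on POS / pronoun / emotion / binary-polarity /
    graded-polarity distributions (3 dataset pairs each), Welch t on
    character counts (control vs depressive users, depressive users vs
    depressive tweets), Mann-Whitney on per-tweet negation counts (3 pairs),
    and GG-corrected mixed ANOVA on the hourly and weekday activity profiles
    (control vs depressive users; the group×level interaction is the
    headline effect).  A Bonferroni-adjusted column is included for
    transparency; the primary p-values are unadjusted.
    """
    rows: list[tuple[str, str, str, StatResult]] = []
    _pair_chi2("pos", pos, rows)
    _pair_chi2("pronouns", pronouns, rows)
    _pair_chi2("emotions", emotions, rows)
    _pair_chi2("polarity_binary", polarity_binary, rows)
    _pair_chi2("polarity_graded", polarity_graded, rows)

    for a, b in (DATASET_PAIRS[0], DATASET_PAIRS[2]):
        res = welch_t(chars[a], chars[b])
        rows.append((f"{a} vs {b}", "characters", "welch_t", res))

    for a, b in DATASET_PAIRS:
        res = mann_whitney_u(negations[a], negations[b])
        rows.append((f"{a} vs {b}", "negations", "mann_whitney_u", res))

    for family, profiles in (("hourly", hourly), ("weekday", weekday)):
        a, b = DATASET_PAIRS[0]
        data = np.vstack([profiles[a], profiles[b]])
        groups = [a] * profiles[a].shape[0] + [b] * profiles[b].shape[0]
        res = mixed_anova_gg(data, groups)["interaction"]
        rows.append((f"{a} vs {b}", family, "mixed_anova_gg", res))

    m = len(rows)
    records = []
    for comparison, family, test, res in rows:
        df1, df2 = (res.df if isinstance(res.df, tuple) else (res.df, np.nan))
        records.append(
            {
                "comparison": comparison,
                "family": family,
                "test": test,
                "statistic": res.statistic,
                "df1": df1,
                "df2": df2,
                "epsilon": res.epsilon if res.epsilon is not None else np.nan,
                "p": res.p_value,
                "p_bonferroni": min(1.0, res.p_value * m),
            }
        )
    return pd.DataFrame.from_records(records)


__all__ = [
    "DATASET_PAIRS",
    "StatResult",
    "SummaryStats",
    "ContingencyTable",
    "chi_square",
    "welch_t",
    "welch_t_raw",
    "mann_whitney_u",
    "gg_epsilon",
    "mixed_anova_gg",
    "run_comparisons",
]
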