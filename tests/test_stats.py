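"""Test-statistic implementations against brute-force and library oracles."""

import numpy as np
import pandas as pd
import pytest

from tuitvig.stats import (
    ContingencyTable,
    SummaryStats,
    chi_square,
    gg_epsilon,
    mann_whitney_u,
    mixed_anova_gg,
    welch_t,
    welch_t_raw,
)


def chi_square_oracle(obs: np.ndarray) -> float:
    """Cell-by-cell margin formula, no vectorization."""
    obs = np.asarray(obs, dtype=float)
    total = obs.sum()
    stat = 0.0
    for i in range(obs.shape[0]):
        for j in range(obs.shape[1]):
            e = obs[i].sum() * obs[:, j].sum() / total
            stat += (obs[i, j] - e) ** 2 / e
    return stat


def mwu_oracle(x, y) -> float:
    """Pairwise comparison count: wins + half-ties for the first sample."""
    u = 0.0
    for xi in x:
        for yj in y:
            u += (xi > yj) + 0.5 * (xi == yj)
    return u


class TestChiSquare:
    def test_homogeneous_table_is_zero(self):
        t = ContingencyTable(("a", "b"), ("x", "y"), np.array([[10, 10], [10, 10]]))
        res = chi_square(t)
        assert res.statistic == 0.0 and res.df == 1.0

    def test_matches_margin_oracle_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            shape = (rng.integers(2, 4), rng.integers(2, 5))
            obs = rng.integers(1, 60, size=shape)
            t = ContingencyTable(
                tuple(f"r{i}" for i in range(shape[0])),
                tuple(f"c{j}" for j in range(shape[1])),
                obs,
            )
            assert chi_square(t).statistic == pytest.approx(
                chi_square_oracle(obs), abs=1e-10
            )

    def test_permutation_invariance(self):
        obs = np.array([[5, 9, 2], [7, 3, 11]])
        t1 = ContingencyTable(("a", "b"), ("x", "y", "z"), obs)
        t2 = ContingencyTable(("b", "a"), ("z", "x", "y"), obs[::-1][:, [2, 0, 1]])
        assert chi_square(t1).statistic == pytest.approx(chi_square(t2).statistic)

    def test_zero_margin_is_error(self):
        t = ContingencyTable(("a", "b"), ("x", "y"), np.array([[0, 5], [0, 7]]))
        with pytest.raises(ValueError, match="margin"):
            chi_square(t)

    def test_degenerate_shapes_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(("a",), ("x", "y"), np.array([[1, 2]]))


class TestWelchT:
    def test_identical_summaries_give_zero(self):
        s = SummaryStats(5.0, 2.0, 30)
        assert welch_t(s, s).statistic == 0.0

    def test_antisymmetric(self):
        a, b = SummaryStats(5.0, 2.0, 30), SummaryStats(4.0, 3.0, 25)
        ra, rb = welch_t(a, b), welch_t(b, a)
        assert ra.statistic == -rb.statistic
        assert ra.p_value == rb.p_value

    def test_raw_and_summary_paths_agree(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 40), rng.normal(0.4, 1.6, 25)
        raw = welch_t_raw(x, y)
        summ = welch_t(SummaryStats.of(x), SummaryStats.of(y))
        assert raw.statistic == pytest.approx(summ.statistic, abs=1e-9)
        assert raw.df == pytest.approx(summ.df, abs=1e-9)

    def test_matches_scipy(self):
        from scipy.stats import ttest_ind

        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 31), rng.normal(0.5, 2, 44)
        mine = welch_t_raw(x, y)
        ref = ttest_ind(x, y, equal_var=False)
        assert mine.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_variance_is_error(self):
        s = SummaryStats(5.0, 0.0, 10)
        with pytest.raises(ValueError, match="variance"):
            welch_t(s, s)


class TestMannWhitney:
    def test_complete_separation(self):
        assert mann_whitney_u([1, 2], [3, 4]).statistic == 0.0

    def test_single_tied_pair_is_half(self):
        assert mann_whitney_u([5.0], [5.0]).statistic == 0.5

    def test_u_matches_pairwise_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            nx, ny = rng.integers(2, 12, size=2)
            x = rng.integers(0, 6, size=nx).astype(float)  # ties likely
            y = rng.integers(0, 6, size=ny).astype(float)
            res = mann_whitney_u(x, y)
            assert res.statistic == pytest.approx(mwu_oracle(x, y), abs=1e-9)

    def test_u_complementarity(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=14), rng.normal(size=17)
        ux = mann_whitney_u(x, y).statistic
        uy = mann_whitney_u(y, x).statistic
        assert ux + uy == pytest.approx(len(x) * len(y))

    def test_exact_p_matches_scipy(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(10)
        for _ in range(30):
            nx, ny = rng.integers(2, 15, size=2)
            x, y = rng.normal(size=nx), rng.normal(size=ny)
            mine = mann_whitney_u(x, y)
            ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_asymptotic_p_matches_scipy_with_ties(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(11)
        x = rng.integers(0, 4, 150).astype(float)
        y = rng.integers(0, 5, 170).astype(float)
        mine = mann_whitney_u(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-9)


class TestMixedAnovaGG:
    def _simulate(self, rng, n1=12, n2=9, L=6, shift=0.0):
        data = np.vstack(
            [
                rng.normal(0, 1, (n1, L)) + rng.normal(0, 1, (n1, 1)),
                rng.normal(shift, 1.3, (n2, L)) + rng.normal(0, 1, (n2, 1)),
            ]
        )
        return data, ["a"] * n1 + ["b"] * n2

    def test_two_levels_give_epsilon_one(self):
        rng = np.random.default_rng(12)
        data, groups = self._simulate(rng, L=2)
        assert gg_epsilon(data, groups) == pytest.approx(1.0)

    def test_compound_symmetry_gives_epsilon_near_one(self):
        rng = np.random.default_rng(13)
        # iid + shared subject effect => compound-symmetric covariance
        subj = rng.normal(0, 2, (600, 1))
        data = subj + rng.normal(0, 1, (600, 5))
        groups = ["a"] * 300 + ["b"] * 300
        assert gg_epsilon(data, groups) >= 0.99

    def test_f_statistics_match_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        data, groups = self._simulate(rng, shift=0.5)
        n, L = data.shape
        mine = mixed_anova_gg(data, groups)
        df = pd.DataFrame(
            {
                "y": data.ravel(),
                "subj": np.repeat(np.arange(n), L),
                "time": np.tile(np.arange(L), n),
                "grp": np.repeat(groups, L),
            }
        )
        ref = pg.mixed_anova(
            df, dv="y", within="time", subject="subj", between="grp", correction=True
        ).set_index("Source")
        assert mine["group"].statistic == pytest.approx(ref.loc["grp", "F"], rel=1e-9)
        assert mine["level"].statistic == pytest.approx(ref.loc["time", "F"], rel=1e-9)
        assert mine["interaction"].statistic == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-9
        )
        # epsilon definitions differ slightly (pooled within-group here)
        assert mine["level"].epsilon == pytest.approx(ref.loc["time", "eps"], abs=0.1)

    def test_null_interaction_rarely_large(self):
        rng = np.random.default_rng(14)
        from scipy.stats import f as fdist

        exceed = 0
        n_rep = 40
        for _ in range(n_rep):
            data, groups = self._simulate(rng)  # same generating process
            res = mixed_anova_gg(data, groups)["interaction"]
            d1, d2 = res.df
            if res.statistic > fdist.ppf(0.95, d1, d2):
                exceed += 1
        assert exceed <= 0.25 * n_rep  # well below always-significant

    def test_incomplete_vectors_rejected(self):
        data = np.ones((4, 3))
        data[0, 1] = np.nan
        with pytest.raises(ValueError, match="incomplete"):
            mixed_anova_gg(data, ["a", "a", "b", "b"])
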