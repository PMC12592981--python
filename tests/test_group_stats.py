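"""Statistical layer: rank tests, ANOVAs, Wilcoxon, qPCR quantification."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from vasomet import group_stats as gs


def make_rm_frame(y: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    n, k = y.shape
    return pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "group": np.repeat(groups, k),
        "time": np.tile(np.arange(k), n),
        "value": y.ravel()})


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        res = gs.kruskal_wallis({"a": [5, 5], "b": [5, 5], "c": [5, 5]})
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_hand_computed_h(self):
        """Ranks 1..9 in blocks of three: H = 12/(N(N+1)) * sum n (Rbar-R)^2
        = 7.2 by direct evaluation."""
        res = gs.kruskal_wallis({"a": [1, 2, 3], "b": [4, 5, 6],
                                 "c": [7, 8, 9]})
        assert res.statistic == pytest.approx(7.2)
        assert res.df == 2.0
        assert res.pvalue == pytest.approx(stats.chi2.sf(7.2, 2))

    def test_chi2_p_close_to_exact_permutation(self):
        """Small samples: the chi-square p stays within 0.05 of the exact
        permutation p over all group relabelings."""
        a, b = [1.2, 3.4, 0.5, 2.2], [4.1, 5.0, 2.9, 6.2]
        pooled = np.array(a + b)
        res = gs.kruskal_wallis({"a": a, "b": b})
        count = 0
        idx = range(8)
        combos = list(combinations(idx, 4))
        for c in combos:
            mask = np.zeros(8, bool)
            mask[list(c)] = True
            h = gs.kruskal_wallis({"a": pooled[mask],
                                   "b": pooled[~mask]}).statistic
            count += h >= res.statistic - 1e-12
        exact_p = count / len(combos)
        assert abs(res.pvalue - exact_p) < 0.05

    @settings(max_examples=25, derandomize=True)
    @given(st.lists(st.integers(-50, 50), min_size=3, max_size=8),
           st.lists(st.integers(-50, 50), min_size=3, max_size=8))
    def test_invariant_under_monotone_transform(self, a, b):
        base = gs.kruskal_wallis({"a": a, "b": b})
        f = lambda xs: [np.exp(0.05 * x) + 3 for x in xs]
        trans = gs.kruskal_wallis({"a": f(a), "b": f(b)})
        assert base.statistic == pytest.approx(trans.statistic, abs=1e-9)


class TestConover:
    def test_identical_groups_all_p_one(self):
        res = gs.conover_posthoc({"a": [3, 3], "b": [3, 3], "c": [3, 3]})
        assert (res.table["p_adj"] == 1.0).all()

    def test_symmetry_of_pairwise_p(self):
        rng = np.random.default_rng(0)
        data = {g: rng.normal(i, 1, 6) for i, g in enumerate("abcd")}
        res = gs.conover_posthoc(data)
        for x, y in combinations("abcd", 2):
            assert gs.conover_pvalue(res, x, y) == gs.conover_pvalue(res, y, x)

    def test_matches_hand_computed_formula(self):
        """Three untied blocks: Rbar = (2, 5, 8), S^2 = 7.5, H = 7.2, so
        t(a,b) = -3 / sqrt(7.5 * (8-7.2)/6 * (2/3)) = -3.674..."""
        data = {"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]}
        res = gs.conover_posthoc(data)
        t_ab = res.table.set_index(["group_a", "group_b"]).loc[("a", "b"),
                                                               "statistic"]
        expected = -3.0 / np.sqrt(7.5 * ((9 - 1 - 7.2) / (9 - 3)) * (2 / 3))
        assert t_ab == pytest.approx(expected)
        assert res.df == 6.0

    def test_four_group_hand_ranks(self):
        """Independent evaluation of the Conover t on paper-and-pencil
        midranks for a 4-group layout with ties."""
        data = {"w": [1.0, 2.0], "x": [2.0, 4.0], "y": [5.0, 6.0],
                "z": [7.0, 8.0]}
        pooled = np.concatenate(list(data.values()))
        ranks = stats.rankdata(pooled)
        n = 2
        rbar = {g: ranks[2 * i:2 * i + 2].mean()
                for i, g in enumerate(data)}
        N, k = 8, 4
        h = gs.kruskal_wallis(data).statistic
        s2 = (np.sum(ranks ** 2) - N * (N + 1) ** 2 / 4) / (N - 1)
        scale = s2 * (N - 1 - h) / (N - k)
        res = gs.conover_posthoc(data)
        for (ga, gb) in combinations(data, 2):
            expected = (rbar[ga] - rbar[gb]) / np.sqrt(scale * (1 / n + 1 / n))
            got = res.table.set_index(["group_a", "group_b"]).loc[(ga, gb),
                                                                  "statistic"]
            assert got == pytest.approx(expected)

    def test_adjusted_p_monotone(self):
        rng = np.random.default_rng(1)
        data = {g: rng.normal(i * 0.5, 1, 5) for i, g in enumerate("abcd")}
        raw = gs.conover_posthoc(data, adjust=None).table
        holm = gs.conover_posthoc(data, adjust="holm").table
        bonf = gs.conover_posthoc(data, adjust="bonferroni").table
        assert (holm["p_adj"] >= raw["p_adj"] - 1e-12).all()
        assert (bonf["p_adj"] >= raw["p_adj"] - 1e-12).all()

    def test_no_significance_when_omnibus_flat(self):
        res = gs.conover_posthoc({"a": [2, 2, 2], "b": [2, 2, 2]})
        assert (res.table["p_adj"] == 1.0).all()


class TestTwoWayAnova:
    @staticmethod
    def _frame(cells, reps=3, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for (a, b), mu in cells.items():
            for _ in range(reps):
                rows.append({"a": a, "b": b,
                             "y": mu + rng.normal(0, noise) if noise else mu})
        return pd.DataFrame(rows)

    def test_flat_design_all_f_zero(self):
        df = self._frame({(a, b): 5.0 for a in "xy" for b in "pqr"})
        res = gs.anova_two_way(df, "y", "a", "b")
        assert (res.table.set_index("index").loc[["a", "b", "a:b"], "F"]
                == 0.0).all()

    def test_additive_design_zero_interaction(self):
        cells = {(a, b): ai * 2.0 + bi for ai, a in enumerate("xy")
                 for bi, b in enumerate("pqr")}
        res = gs.anova_two_way(self._frame(cells), "y", "a", "b")
        assert res.statistic == 0.0  # interaction F
        assert res.pvalue == 1.0

    def test_matches_hand_sum_of_squares(self):
        """Balanced 2x3: F values against an explicit SS decomposition."""
        rng = np.random.default_rng(3)
        cells = {(a, b): rng.normal(0, 2)
                 for a in "xy" for b in "pqr"}
        df = self._frame(cells, reps=4, noise=1.0, seed=3)
        res = gs.anova_two_way(df, "y", "a", "b")
        y = df["y"].to_numpy()
        grand = y.mean()
        ss_a = sum(len(d) * (d["y"].mean() - grand) ** 2
                   for _, d in df.groupby("a"))
        ss_b = sum(len(d) * (d["y"].mean() - grand) ** 2
                   for _, d in df.groupby("b"))
        ss_cells = sum(len(d) * (d["y"].mean() - grand) ** 2
                       for _, d in df.groupby(["a", "b"]))
        ss_ab = ss_cells - ss_a - ss_b
        ss_err = sum(((d["y"] - d["y"].mean()) ** 2).sum()
                     for _, d in df.groupby(["a", "b"]))
        table = res.table.set_index("index")
        f_a = (ss_a / 1) / (ss_err / 18)
        f_b = (ss_b / 2) / (ss_err / 18)
        f_ab = (ss_ab / 2) / (ss_err / 18)
        assert table.loc["a", "F"] == pytest.approx(f_a)
        assert table.loc["b", "F"] == pytest.approx(f_b)
        assert table.loc["a:b", "F"] == pytest.approx(f_ab)

    def test_empty_cell_rejected(self):
        df = self._frame({("x", "p"): 1.0, ("x", "q"): 2.0, ("y", "p"): 3.0})
        with pytest.raises(gs.StatsError, match="empty cells"):
            gs.anova_two_way(df, "y", "a", "b")

    def test_tukey_table_attached(self):
        rng = np.random.default_rng(4)
        cells = {(a, b): rng.normal(0, 2) for a in "xy" for b in "pq"}
        df = self._frame(cells, reps=5, noise=1.0, seed=4)
        res = gs.anova_two_way(df, "y", "a", "b", tukey=True)
        assert len(res.extra["tukey"]) == 6  # C(4 cells, 2) comparisons


class TestRmAnova:
    def test_compound_symmetry_epsilon(self):
        """The epsilon formula on a known compound-symmetric covariance is
        exactly 1; the n=50 sample estimate sits near 1 minus its known
        small-sample bias of about (k-1)/n."""
        k = 4
        analytic = gs.gg_epsilon(np.eye(k) + 0.5 * np.ones((k, k)))
        assert analytic == pytest.approx(1.0)
        rng = np.random.default_rng(0)
        y = rng.normal(size=(50, 4)) + rng.normal(size=(50, 1))
        groups = np.repeat(["A", "B"], 25)
        res = gs.rm_anova_two_way(make_rm_frame(y, groups))
        assert 1.0 - 2 * (k - 1) / 50 <= res.extra["eps"] <= 1.0

    def test_group_shift_detected_time_flat(self):
        """A pure between-group shift: large group F, null time and
        interaction. Power check at d=2 with 10 subjects/group."""
        rng = np.random.default_rng(1)
        detected = 0
        for rep in range(20):
            y = rng.normal(size=(20, 4))
            y[10:] += 2.0
            groups = np.repeat(["A", "B"], 10)
            res = gs.rm_anova_two_way(make_rm_frame(y, groups))
            tab = res.table.set_index("effect")
            detected += tab.loc["group", "p"] < 0.05
            assert res.pvalue > 0.001  # interaction stays unremarkable
        assert detected >= 18  # >= 90% power

    def test_matches_pingouin_mixed_anova(self):
        import pingouin as pg

        rng = np.random.default_rng(2)
        y = rng.normal(size=(12, 4)) + np.linspace(0, 1, 4)
        y[6:] += 0.8
        groups = np.repeat(["A", "B"], 6)
        df = make_rm_frame(y, groups)
        mine = gs.rm_anova_two_way(df, correction=None).table.set_index("effect")
        ref = pg.mixed_anova(df, dv="value", within="time",
                             subject="subject", between="group")
        ref = ref.set_index("Source")
        assert mine.loc["group", "F"] == pytest.approx(
            ref.loc["group", "F"])
        assert mine.loc["time", "F"] == pytest.approx(ref.loc["time", "F"])
        assert mine.loc["timexgroup", "F"] == pytest.approx(
            ref.loc["Interaction", "F"])

    def test_unbalanced_within_rejected(self):
        df = make_rm_frame(np.zeros((4, 3)), np.repeat(["A", "B"], 2))
        df = df.drop(index=0)
        with pytest.raises(gs.StatsError, match="unbalanced"):
            gs.rm_anova_two_way(df)

    def test_fractional_dfs_under_correction(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=(16, 5))
        y[:, 0] += y[:, 1] * 2  # break sphericity
        res = gs.rm_anova_two_way(make_rm_frame(y, np.repeat(["A", "B"], 8)))
        df1, df2 = res.df
        assert res.extra["eps"] < 1.0
        assert df1 < (2 - 1) * (5 - 1)


class TestWilcoxon:
    def test_exact_matches_sign_flip_enumeration(self):
        """n=8: exact p equals exhaustive enumeration over 2^8 signs."""
        from itertools import product

        d = np.array([1.5, -2.3, 0.7, 3.1, -0.2, 1.1, 2.2, -0.9])
        res = gs.wilcoxon_signed_rank(d)
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        total = ranks.sum()
        w_min_obs = min(w_obs, total - w_obs)
        count = 0
        for signs in product((0, 1), repeat=8):
            w = sum(r for r, s in zip(ranks, signs) if s)
            if min(w, total - w) <= w_min_obs:
                count += 1
        assert res.pvalue == pytest.approx(count / 2 ** 8)
        assert res.extra["method"] == "exact"

    def test_antisymmetric_differences_p_near_one(self):
        d = np.array([-1.0, 1.0, -2.0, 2.0, -3.0, 3.0, -4.0, 4.0])
        res = gs.wilcoxon_signed_rank(d)
        assert res.pvalue > 0.9

    def test_pairing_shift_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(1, 1, 10)
        y = rng.normal(0, 1, 10)
        a = gs.wilcoxon_signed_rank(x, y)
        b = gs.wilcoxon_signed_rank(x + 100.0, y + 100.0)
        assert a.statistic == pytest.approx(b.statistic)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(gs.StatsError):
            gs.wilcoxon_signed_rank(np.zeros(6))


class TestDdctRq:
    @staticmethod
    def _records(dct_by_group, reps=2):
        rows = []
        for g, dct in dct_by_group.items():
            for i in range(3):
                for _ in range(reps):
                    rows.append({"sample": f"{g}{i}", "group": g,
                                 "ct_target": 20.0 + dct, "ct_reference": 20.0})
        return pd.DataFrame(rows)

    def test_calibrator_group_rq_one(self):
        _, per_group = gs.ddct_rq(self._records({"wt": 2.0, "mut": 2.0}), "wt")
        row = per_group.set_index("group")
        assert row.loc["mut", "ddct"] == pytest.approx(0.0)
        assert row.loc["mut", "rq"] == pytest.approx(1.0)

    def test_ddct_minus_one_doubles_rq(self):
        _, per_group = gs.ddct_rq(self._records({"wt": 2.0, "mut": 1.0}), "wt")
        assert per_group.set_index("group").loc["mut", "rq"] \
            == pytest.approx(2.0)

    def test_closed_form_tenth(self):
        _, per_group = gs.ddct_rq(
            self._records({"wt": 0.0, "mut": 3.3219}), "wt")
        assert per_group.set_index("group").loc["mut", "rq"] \
            == pytest.approx(0.1, abs=1e-3)

    def test_technical_replicates_averaged_first(self):
        rec = pd.DataFrame({
            "sample": ["s1", "s1", "s2"], "group": ["wt", "wt", "wt"],
            "ct_target": [20.0, 22.0, 21.0], "ct_reference": [15.0, 15.0, 15.0]})
        per_sample, _ = gs.ddct_rq(rec, "wt")
        assert len(per_sample) == 2
        assert per_sample.set_index("sample").loc["s1", "dct"] \
            == pytest.approx(6.0)

    def test_missing_reference_rejected(self):
        rec = pd.DataFrame({"sample": ["s"], "group": ["wt"],
                            "ct_target": [20.0], "ct_reference": [np.nan]})
        with pytest.raises(gs.StatsError):
            gs.ddct_rq(rec, "wt")
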