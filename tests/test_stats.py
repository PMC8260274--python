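"""First-principles statistics vs independent oracles.

Each procedure is checked against a computation that shares no code with
the implementation: full enumeration via pairwise comparisons for the rank
test, textbook cell-mean sums of squares for the ANOVAs, closed-form hand
values for the scalar statistics, and scipy/statsmodels as external
cross-checks.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from spinedyn import (ValidationError, cohens_d, mann_whitney_u, pearson_r,
                      rm_mixed_anova, t_test_unpaired, two_way_anova)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def mwu_enumeration_oracle(x, y):
    """Exact two-sided Mann-Whitney p by enumerating every assignment of the
    pooled values and counting pairwise wins (no ranks involved)."""
    pooled = list(x) + list(y)
    nx = len(x)

    def u_stat(xs, ys):
        return sum((a > b) + 0.5 * (a == b) for a in xs for b in ys)

    u_obs = u_stat(x, y)
    us = []
    for idx in itertools.combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_stat(xs, ys))
    us = np.array(us)
    p_low = (us <= u_obs + 1e-9).mean()
    p_high = (us >= u_obs - 1e-9).mean()
    return min(1.0, 2 * min(p_low, p_high))


def balanced_two_way_ss_oracle(y, a, b):
    """Textbook cell-mean sums of squares for a balanced two-way design."""
    y = np.asarray(y, float)
    a = np.asarray(a)
    b = np.asarray(b)
    grand = y.mean()
    levels_a, levels_b = sorted(set(a)), sorted(set(b))
    n_cell = len(y) / (len(levels_a) * len(levels_b))
    ss_a = sum(y[a == la].size * (y[a == la].mean() - grand) ** 2
               for la in levels_a)
    ss_b = sum(y[b == lb].size * (y[b == lb].mean() - grand) ** 2
               for lb in levels_b)
    ss_ab = 0.0
    ss_err = 0.0
    for la in levels_a:
        for lb in levels_b:
            cell = y[(a == la) & (b == lb)]
            ss_ab += len(cell) * (cell.mean() - y[a == la].mean()
                                  - y[b == lb].mean() + grand) ** 2
            ss_err += ((cell - cell.mean()) ** 2).sum()
    df_err = len(y) - len(levels_a) * len(levels_b)
    return ss_a, ss_b, ss_ab, ss_err, df_err


def split_plot_ss_oracle(df, dv, subject, within, fa, fb):
    """Classic split-plot sums of squares from raw cell totals (balanced,
    no blocking term)."""
    y = df[dv].to_numpy(float)
    grand = y.mean()
    subj_means = df.groupby(subject)[dv].mean()
    T = df[within].nunique()
    N = df[subject].nunique()
    meta = df.drop_duplicates(subject).set_index(subject)
    ss_between_subj = T * ((subj_means - grand) ** 2).sum()

    def group_ss(col):
        means = df.groupby(col)[dv].mean()
        counts = meta.groupby(col).size() * T
        return float((counts * (means - grand) ** 2).sum())

    ss_g, ss_w = group_ss(fa), group_ss(fb)
    cell_means = df.groupby([fa, fb])[dv].mean()
    fa_means = df.groupby(fa)[dv].mean()
    fb_means = df.groupby(fb)[dv].mean()
    ss_gw = 0.0
    for (la, lb), m in cell_means.items():
        n_cell = ((meta[fa] == la) & (meta[fb] == lb)).sum() * T
        ss_gw += n_cell * (m - fa_means[la] - fb_means[lb] + grand) ** 2
    ss_subj_err = ss_between_subj - ss_g - ss_w - ss_gw
    trial_means = df.groupby(within)[dv].mean()
    ss_trial = N * ((trial_means - grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_werr = ss_total - ss_between_subj - ss_trial
    n_cells = df.groupby([fa, fb]).ngroups
    return {
        "genotype": (ss_g, 1, ss_subj_err, N - n_cells),
        "treatment": (ss_w, 1, ss_subj_err, N - n_cells),
        "genotype:treatment": (ss_gw, 1, ss_subj_err, N - n_cells),
        "trial": (float(ss_trial), T - 1, float(ss_werr), (N - 1) * (T - 1)),
    }


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

class TestMannWhitneyU:
    def test_complete_separation_small_samples(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6], mode="exact")
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2 * (1/20)

    def test_total_ties_give_p_one(self):
        res = mann_whitney_u([5, 5, 5], [5, 5, 5])
        assert res.p_value == pytest.approx(1.0)

    def test_exact_matches_enumeration_oracle_bit_exactly(self, rng):
        for _ in range(25):
            nx, ny = rng.integers(2, 7, 2)
            x = np.round(rng.normal(size=nx), 1)  # rounding creates ties
            y = np.round(rng.normal(size=ny), 1)
            res = mann_whitney_u(x, y, mode="exact")
            assert res.p_value == mwu_enumeration_oracle(list(x), list(y))

    def test_exact_matches_scipy_without_ties(self, rng):
        for _ in range(10):
            x = rng.normal(size=5)
            y = rng.normal(size=6)
            ours = mann_whitney_u(x, y, mode="exact")
            ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                           method="exact")
            assert ours.statistic == pytest.approx(ref.statistic)
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approx_close_to_scipy(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(0.5, 1.0, size=25)
        ours = mann_whitney_u(x, y, mode="normal_approx")
        ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                       method="asymptotic")
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_null_rejection_rate_bounded(self, rng):
        """Exact-test size: under a continuous null the rejection rate at
        alpha = 0.05 stays below 0.05 + 3 MC-SE over 2000 simulations."""
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            rejections += mann_whitney_u(x, y).p_value < 0.05
        se = math.sqrt(0.05 * 0.95 / n_sim)
        assert rejections / n_sim <= 0.05 + 3 * se

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])


# ---------------------------------------------------------------------------
# t test, Cohen's d, Pearson r
# ---------------------------------------------------------------------------

class TestScalarTests:
    def test_identical_samples_t_zero(self):
        res = t_test_unpaired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_degenerate_variance_errors(self):
        with pytest.raises(ValidationError, match="degenerate variance"):
            t_test_unpaired([0.0, 0.0], [1.0, 1.0])

    def test_worked_example_closed_form(self):
        """x = [1,2,3,4], y = [3,5,7]: pooled s^2 = (5/3*2 + 8) / 5 = 34/15,
        t = (2.5 - 5)/sqrt(34/15 * (1/4 + 1/3)) = -2.1757..., df = 5."""
        x, y = [1.0, 2.0, 3.0, 4.0], [3.0, 5.0, 7.0]
        sp2 = (3 * np.var(x, ddof=1) + 2 * np.var(y, ddof=1)) / 5
        t_hand = (np.mean(x) - np.mean(y)) / math.sqrt(sp2 * (1 / 4 + 1 / 3))
        res = t_test_unpaired(x, y)
        assert res.statistic == pytest.approx(t_hand, abs=1e-12)
        ref = scipy.stats.ttest_ind(x, y)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)
        assert res.df == (5.0,)

    def test_cohens_d_hand_examples(self):
        # means 1 apart, pooled SD 1
        assert cohens_d([2.0, 4.0], [1.0, 3.0]) == pytest.approx(
            1.0 / math.sqrt(2.0), abs=1e-12)
        assert cohens_d([1.0, 2.0], [1.0, 2.0]) == 0.0
        x = [0.0, 1.0, 2.0]
        y = [-1.0, 0.0, 1.0]  # pooled SD = 1, mean diff = 1
        assert cohens_d(x, y) == pytest.approx(1.0, abs=1e-12)

    def test_pearson_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, 2 * x + 1).statistic == pytest.approx(1.0)
        assert pearson_r(x, -x).statistic == pytest.approx(-1.0)

    def test_pearson_hand_computation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        xc, yc = x - x.mean(), y - y.mean()
        r_hand = (xc * yc).sum() / math.sqrt((xc ** 2).sum() * (yc ** 2).sum())
        res = pearson_r(x, y)
        assert res.statistic == pytest.approx(r_hand, abs=1e-12)
        ref_r, ref_p = scipy.stats.pearsonr(x, y)
        assert res.statistic == pytest.approx(ref_r, abs=1e-12)
        assert res.p_value == pytest.approx(ref_p, abs=1e-10)

    def test_pearson_constant_input_rejected(self):
        with pytest.raises(ValidationError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# Two-way ANOVA
# ---------------------------------------------------------------------------

def toy_design(n_cell=3, seed=0, unbalanced=False):
    rng = np.random.default_rng(seed)
    rows = []
    for a in ("a1", "a2"):
        for b in ("b1", "b2"):
            n = n_cell + (1 if unbalanced and a == "a2" else 0)
            for _ in range(n):
                rows.append((a, b, rng.normal(loc=(a == "a2") * 1.0
                                              + (b == "b2") * 0.5)))
    df = pd.DataFrame(rows, columns=["a", "b", "y"])
    return df


class TestTwoWayAnova:
    def test_constant_response_all_f_zero(self):
        df = toy_design()
        res = two_way_anova(np.ones(len(df)), df["a"], df["b"])
        effects = res.table[res.table["effect"] != "residual"]
        assert (effects["F"] == 0.0).all()

    def test_exact_additivity_zero_interaction_infinite_mains(self):
        rows = [("a1", "b1", 1.0), ("a1", "b2", 3.0),
                ("a2", "b1", 2.0), ("a2", "b2", 4.0)] * 2
        df = pd.DataFrame(rows, columns=["a", "b", "y"])
        res = two_way_anova(df["y"], df["a"], df["b"])
        t = res.table.set_index("effect")
        assert t.loc["A:B", "F"] == 0.0
        assert math.isinf(t.loc["A", "F"]) and t.loc["A", "p_value"] == 0.0

    def test_balanced_toy_matches_cell_mean_oracle(self):
        df = toy_design(n_cell=4, seed=3)
        res = two_way_anova(df["y"], df["a"], df["b"])
        ss_a, ss_b, ss_ab, ss_err, df_err = balanced_two_way_ss_oracle(
            df["y"], df["a"], df["b"])
        t = res.table.set_index("effect")
        assert t.loc["A", "F"] == pytest.approx(
            (ss_a / 1) / (ss_err / df_err), abs=1e-10)
        assert t.loc["B", "F"] == pytest.approx(
            (ss_b / 1) / (ss_err / df_err), abs=1e-10)
        assert t.loc["A:B", "F"] == pytest.approx(
            (ss_ab / 1) / (ss_err / df_err), abs=1e-10)

    def test_unbalanced_matches_statsmodels_type2(self):
        smf = pytest.importorskip("statsmodels.formula.api")
        from statsmodels.stats.anova import anova_lm
        df = toy_design(n_cell=3, seed=7, unbalanced=True)
        res = two_way_anova(df["y"], df["a"], df["b"])
        fit = smf.ols("y ~ C(a) * C(b)", data=df).fit()
        ref = anova_lm(fit, typ=2)
        t = res.table.set_index("effect")
        assert t.loc["A", "F"] == pytest.approx(ref.loc["C(a)", "F"],
                                                rel=1e-8)
        assert t.loc["B", "F"] == pytest.approx(ref.loc["C(b)", "F"],
                                                rel=1e-8)
        assert t.loc["A:B", "F"] == pytest.approx(
            ref.loc["C(a):C(b)", "F"], rel=1e-8)

    def test_empty_cell_named_in_error(self):
        df = toy_design()
        df = df[~((df["a"] == "a2") & (df["b"] == "b2"))]
        with pytest.raises(ValidationError, match="a2.*b2"):
            two_way_anova(df["y"], df["a"], df["b"])

    def test_tukey_flags_separated_cell(self):
        df = toy_design(n_cell=6, seed=1)
        df.loc[(df["a"] == "a2") & (df["b"] == "b2"), "y"] += 30.0
        res = two_way_anova(df["y"], df["a"], df["b"], tukey=True)
        assert res.tukey is not None and len(res.tukey) == 6
        big = res.tukey[res.tukey["cell_1"].str.contains("a2/b2") |
                        res.tukey["cell_2"].str.contains("a2/b2")]
        assert (big["p_value"] < 0.01).all()

    @given(shift=st.floats(-50, 50), scale=st.floats(0.1, 20))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance_of_f(self, shift, scale):
        df = toy_design(n_cell=3, seed=11)
        base = two_way_anova(df["y"], df["a"], df["b"]).table
        moved = two_way_anova(df["y"] * scale + shift, df["a"],
                              df["b"]).table
        assert np.allclose(base["F"][:3].astype(float),
                           moved["F"][:3].astype(float), rtol=1e-7)


# ---------------------------------------------------------------------------
# Split-plot repeated-measures ANOVA
# ---------------------------------------------------------------------------

def split_plot_data(n_per_cell=4, trials=3, seed=0, effects=None,
                    trial_slope=0.0):
    rng = np.random.default_rng(seed)
    effects = effects or {}
    rows = []
    s = 0
    for g in ("WT", "MUT"):
        for w in ("VEH", "SL327"):
            for _ in range(n_per_cell):
                s += 1
                base = rng.normal(scale=1.0) + effects.get((g, w), 0.0)
                for t in range(1, trials + 1):
                    rows.append((f"s{s:02d}", g, w, f"L{s % 3}", t,
                                 base + trial_slope * t + rng.normal(scale=0.5)))
    return pd.DataFrame(rows, columns=["animal_id", "genotype", "treatment",
                                       "litter", "trial", "y"])


class TestRmMixedAnova:
    def kw(self, litter=None):
        return dict(dv="y", subject="animal_id", within="trial",
                    between=("genotype", "treatment"), litter=litter)

    def test_constant_responses_all_f_zero(self):
        df = split_plot_data()
        df["y"] = 7.0
        table = rm_mixed_anova(df, **self.kw()).set_index("effect")
        for eff in ("genotype", "treatment", "genotype:treatment", "trial"):
            assert table.loc[eff, "F"] == 0.0

    def test_pure_within_trend(self):
        df = split_plot_data(seed=5, trial_slope=4.0)
        table = rm_mixed_anova(df, **self.kw()).set_index("effect")
        assert table.loc["trial", "F"] > 20
        assert table.loc["trial", "p_value"] < 1e-4
        assert table.loc["genotype", "p_value"] > 0.01  # no group effect

    def test_matches_explicit_ss_oracle(self):
        df = split_plot_data(n_per_cell=4, trials=3, seed=9,
                             effects={("MUT", "VEH"): 2.0}, trial_slope=1.0)
        table = rm_mixed_anova(df, **self.kw()).set_index("effect")
        oracle = split_plot_ss_oracle(df, "y", "animal_id", "trial",
                                      "genotype", "treatment")
        for eff, (ss, df1, ss_err, df2) in oracle.items():
            f_oracle = (ss / df1) / (ss_err / df2)
            assert table.loc[eff, "F"] == pytest.approx(f_oracle, abs=1e-10)
            assert table.loc[eff, "df1"] == df1
            assert table.loc[eff, "df2"] == df2

    def test_litter_blocking_absorbs_litter_variance(self):
        df = split_plot_data(n_per_cell=4, seed=3)
        litter_shift = {"L0": 0.0, "L1": 5.0, "L2": -5.0}
        df["y"] = df["y"] + df["litter"].map(litter_shift)
        with_block = rm_mixed_anova(df, **self.kw(litter="litter")) \
            .set_index("effect")
        without = rm_mixed_anova(df, **self.kw()).set_index("effect")
        # blocking removes litter variance from the subject error term
        assert with_block.loc["subjects(residual)", "ss"] < \
            without.loc["subjects(residual)", "ss"]
        assert "litter" in with_block.index

    def test_missing_trial_listed_in_error(self):
        df = split_plot_data()
        df = df[~((df["animal_id"] == "s01") & (df["trial"] == 2))]
        with pytest.raises(ValidationError, match="s01"):
            rm_mixed_anova(df, **self.kw())

    def test_affine_invariance(self):
        df = split_plot_data(seed=13, effects={("MUT", "VEH"): 1.0})
        base = rm_mixed_anova(df, **self.kw())
        df2 = df.assign(y=df["y"] * 3.0 + 100.0)
        moved = rm_mixed_anova(df2, **self.kw())
        f1 = base[base["F"].notna()]["F"].to_numpy(float)
        f2 = moved[moved["F"].notna()]["F"].to_numpy(float)
        assert np.allclose(f1, f2, rtol=1e-8)

    def test_gg_correction_shrinks_trial_df(self):
        df = split_plot_data(seed=21, trial_slope=2.0)
        plain = rm_mixed_anova(df, **self.kw()).set_index("effect")
        gg = rm_mixed_anova(df, gg_correction=True, **self.kw()) \
            .set_index("effect")
        assert gg.loc["trial", "df1"] <= plain.loc["trial", "df1"]
        assert gg.loc["trial", "F"] == pytest.approx(plain.loc["trial", "F"])
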