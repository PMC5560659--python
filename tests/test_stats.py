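import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from zebraplate.stats import (
    ComparisonDesign,
    bonferroni,
    compare_epochs,
    gg_epsilon,
    mauchly,
    rm_anova,
    welch_t,
)


def welch_oracle(a, b):
    """Textbook Welch formulas, independent of the implementation path."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return t, df, p


class TestWelchT:
    def test_identical_samples(self):
        r = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0.0
        assert r.p_raw == pytest.approx(1.0)

    def test_textbook_example(self):
        # a = 1..5, b = 2..6: equal variances 2.5, mean difference -1
        # -> t = -1 exactly, Welch-Satterthwaite df = 8, p = 0.34659...
        r = welch_t([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert abs(r.t - (-1.0)) < 1e-10
        assert abs(r.df - 8.0) < 1e-10
        assert abs(r.p_raw - 0.34659350708733416) < 1e-6
        t, df, p = welch_oracle([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert r.t == pytest.approx(t, abs=1e-12)
        assert r.df == pytest.approx(df, abs=1e-12)
        assert r.p_raw == pytest.approx(p, abs=1e-12)

    def test_swap_negates_t_keeps_p(self):
        a, b = [0.1, 0.4, 0.3, 0.9], [0.5, 0.6, 0.8]
        r_ab = welch_t(a, b)
        r_ba = welch_t(b, a)
        assert r_ab.t == pytest.approx(-r_ba.t)
        assert r_ab.p_raw == pytest.approx(r_ba.p_raw)

    def test_zero_variance_limits(self):
        same = welch_t([2.0, 2.0], [2.0, 2.0])
        assert (same.t, same.p_raw) == (0.0, 1.0)
        diff = welch_t([2.0, 2.0], [3.0, 3.0])
        assert diff.p_raw == 0.0 and diff.t == -math.inf

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError, match="insufficient n"):
            welch_t([1.0], [1.0, 2.0])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_matches_oracle_on_random_samples(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, rng.integers(2, 12))
        b = rng.normal(0.3, 2, rng.integers(2, 12))
        r = welch_t(a, b)
        t, df, p = welch_oracle(a, b)
        assert r.t == pytest.approx(t, abs=1e-10)
        assert r.df == pytest.approx(df, abs=1e-10)
        assert r.p_raw == pytest.approx(p, abs=1e-10)


class TestBonferroni:
    def test_multiplies_and_caps(self):
        assert bonferroni([0.004], 2) == [0.008]
        assert bonferroni([0.9], 3) == [1.0]
        assert bonferroni([0.2, 0.01], 2) == [pytest.approx(0.4), pytest.approx(0.02)]

    def test_family_of_one_unchanged(self):
        assert bonferroni([0.123], 1) == [pytest.approx(0.123)]

    def test_invalid_family_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.5], 0)
        with pytest.raises(ValueError):
            bonferroni([0.5, 0.6], 1)


def gg_oracle(x):
    """Brute-force Greenhouse-Geisser epsilon from the covariance definition."""
    x = np.asarray(x, float)
    n, k = x.shape
    s = np.cov(x, rowvar=False, ddof=1)
    dc = s - s.mean(axis=1, keepdims=True) - s.mean(axis=0, keepdims=True) + s.mean()
    lam = np.linalg.eigvalsh(dc)
    lam = lam[lam > 1e-12]
    return float(lam.sum() ** 2 / ((k - 1) * (lam**2).sum()))


FIXED_6x4 = np.array(
    [
        [3, 5, 9, 4],
        [4, 6, 12, 5],
        [5, 4, 10, 6],
        [3, 7, 11, 3],
        [6, 5, 13, 7],
        [4, 6, 9, 5],
    ],
    dtype=float,
)


class TestGGEpsilon:
    def test_two_levels_give_epsilon_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(8, 2))
        assert gg_epsilon(x) == pytest.approx(1.0)

    def test_compound_symmetry_gives_epsilon_one(self):
        # equal variances + equal covariances = sphericity holds exactly
        rng = np.random.default_rng(2)
        subj = rng.normal(0, 2, size=(40, 1))
        x = subj + rng.normal(0, 1, size=(40, 5))
        # construct exact compound symmetry instead of sampling noise:
        cs = np.eye(5) * 2.0 + 1.0
        y = rng.multivariate_normal(np.zeros(5), cs, size=500)
        # the estimator works on the empirical covariance; feed it a matrix
        # whose empirical covariance is exactly compound symmetric
        l = np.linalg.cholesky(cs)
        emp = np.cov(y, rowvar=False, ddof=1)
        y_exact = (y - y.mean(0)) @ np.linalg.inv(np.linalg.cholesky(emp)).T @ l.T
        assert gg_epsilon(y_exact) == pytest.approx(1.0, abs=1e-10)

    def test_fixed_matrix_matches_eigen_oracle(self):
        assert gg_epsilon(FIXED_6x4) == pytest.approx(gg_oracle(FIXED_6x4), abs=1e-12)

    def test_matches_pingouin_on_fixed_matrix(self):
        pg = pytest.importorskip("pingouin")
        eps_pg = pg.epsilon(pd.DataFrame(FIXED_6x4), correction="gg")
        assert gg_epsilon(FIXED_6x4) == pytest.approx(float(eps_pg), abs=1e-8)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000), st.integers(3, 6), st.integers(4, 12))
    def test_bounds_hold_for_any_matrix(self, seed, k, n):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n, k)) * rng.uniform(0.5, 3, size=k)
        eps = gg_epsilon(x)
        assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            gg_epsilon(np.ones((5, 1)))


class TestMauchly:
    def test_two_levels_trivially_spherical(self):
        assert mauchly(np.random.default_rng(0).normal(size=(6, 2))) == (1.0, 1.0)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        spher = pg.sphericity(pd.DataFrame(FIXED_6x4), method="mauchly")
        w, p = mauchly(FIXED_6x4)
        assert w == pytest.approx(float(spher.W), abs=1e-8)
        assert p == pytest.approx(float(spher.pval), abs=1e-8)


class TestRMAnova:
    def test_zero_condition_effect(self):
        x = np.tile(np.array([[1.0], [2.0], [5.0], [3.0]]), (1, 4))
        r = rm_anova(x)
        assert r.F == 0.0
        assert r.p_uncorrected == 1.0

    def test_k2_equals_paired_t_squared(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(10, 2))
        r = rm_anova(x)
        t_paired = sps.ttest_rel(x[:, 0], x[:, 1])
        assert abs(r.F - t_paired.statistic**2) < 1e-8
        assert r.p_uncorrected == pytest.approx(t_paired.pvalue, abs=1e-12)

    def test_df_structure(self):
        r = rm_anova(FIXED_6x4)
        assert r.df1 == 3.0
        assert r.df2 == 15.0
        assert r.df1_gg == pytest.approx(r.epsilon_gg * 3.0)
        assert r.df2_gg == pytest.approx(r.epsilon_gg * 15.0)

    def test_matches_pingouin_with_gg_correction(self):
        pg = pytest.importorskip("pingouin")
        df = pd.DataFrame(FIXED_6x4).reset_index().melt("index", var_name="level")
        res = pg.rm_anova(data=df, dv="value", within="level", subject="index", correction=True)
        r = rm_anova(FIXED_6x4, always_gg=True)
        assert r.F == pytest.approx(float(res["F"].iloc[0]), abs=1e-8)
        assert r.p_gg == pytest.approx(float(res["p_GG_corr"].iloc[0]), abs=1e-8)
        assert r.epsilon_gg == pytest.approx(float(res["eps"].iloc[0]), abs=1e-8)

    def test_large_level_effect_detected(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(12, 4)) + np.array([0.0, 0.0, 2.0, 2.0])
        r = rm_anova(x, always_gg=True)
        assert r.p_gg < 0.01

    def test_incomplete_matrix_rejected(self):
        x = FIXED_6x4.copy()
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="incomplete"):
            rm_anova(x)


def summary_table(values_by_epoch):
    rows = []
    for epoch, vals in values_by_epoch.items():
        for roi, v in enumerate(vals):
            rows.append({"roi": roi, "epoch": epoch, "pct_cw": v})
    return pd.DataFrame(rows)


class TestCompareEpochs:
    def test_pairwise_with_family_size(self):
        rng = np.random.default_rng(5)
        tbl = summary_table(
            {
                "cw": 0.9 + rng.normal(0, 0.02, 10),
                "ccw": 0.1 + rng.normal(0, 0.02, 10),
            }
        )
        design = ComparisonDesign(metric="pct_cw", pairs=(("cw", "ccw"),), m=2)
        rep = compare_epochs(tbl, design)
        row = rep.pairwise.iloc[0]
        assert row["p_adj"] == pytest.approx(min(1.0, row["p_raw"] * 2))
        assert row["significant"]

    def test_single_epoch_family_reports_raw_p(self):
        rng = np.random.default_rng(6)
        tbl = summary_table({"a": rng.normal(0.5, 0.1, 6), "b": rng.normal(0.5, 0.1, 6)})
        design = ComparisonDesign(metric="pct_cw", pairs=(("a", "b"),), m=1)
        rep = compare_epochs(tbl, design)
        row = rep.pairwise.iloc[0]
        assert row["p_adj"] == pytest.approx(row["p_raw"])

    def test_rm_anova_over_repeated_epochs(self):
        rng = np.random.default_rng(7)
        tbl = summary_table(
            {
                "cw1": 0.8 + rng.normal(0, 0.05, 8),
                "ccw1": 0.2 + rng.normal(0, 0.05, 8),
                "cw2": 0.8 + rng.normal(0, 0.05, 8),
                "ccw2": 0.2 + rng.normal(0, 0.05, 8),
            }
        )
        design = ComparisonDesign(
            metric="pct_cw", rm_epochs=("cw1", "ccw1", "cw2", "ccw2"), always_gg=True
        )
        rep = compare_epochs(tbl, design)
        assert rep.anova is not None
        assert rep.anova.p < 0.01
        assert "eps_GG" in rep.to_text()

    def test_mismatched_well_sets_rejected(self):
        tbl = summary_table({"a": [0.1, 0.2, 0.3], "b": [0.1, 0.2, 0.3]})
        tbl = tbl.drop(tbl[(tbl.epoch == "b") & (tbl.roi == 2)].index)
        design = ComparisonDesign(pairs=(("a", "b"),))
        with pytest.raises(ValueError, match="well sets differ"):
            compare_epochs(tbl, design)

    def test_unknown_epoch_rejected(self):
        tbl = summary_table({"a": [0.1, 0.2], "b": [0.3, 0.4]})
        with pytest.raises(ValueError, match="unknown epoch"):
            compare_epochs(tbl, ComparisonDesign(pairs=(("a", "zzz"),)))
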