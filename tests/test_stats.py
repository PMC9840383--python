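"""Repeated-measures inference vs independent reference implementations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fiberphot import (
    dunnett_vs_control,
    paired_t,
    rm_anova_oneway,
    rm_anova_twoway_interaction,
    unpaired_t,
)

pingouin = pytest.importorskip("pingouin")


def _long_format(X):
    n, k = X.shape
    return pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "level": np.tile([f"l{j}" for j in range(k)], n),
        "y": X.ravel(),
    })


class TestOnewayRM:
    def test_identical_columns_give_zero_F(self):
        X = np.tile(np.array([[1.0], [2.0], [5.0]]), (1, 4))
        res = rm_anova_oneway(X)
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_two_level_F_equals_paired_t_squared(self):
        X = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 5.0]])
        res = rm_anova_oneway(X)
        t = paired_t(X[:, 1], X[:, 0])
        assert res.F == pytest.approx(t.t**2, abs=1e-10)
        assert res.p == pytest.approx(t.p, abs=1e-10)

    def test_degrees_of_freedom(self):
        X = np.random.default_rng(0).normal(size=(14, 4))
        res = rm_anova_oneway(X)
        assert (res.df1, res.df2) == (3, 39)

    def test_matches_reference_implementation(self, rng):
        """F and p agree with pingouin's RM ANOVA on random designs."""
        for _ in range(50):
            n = int(rng.integers(3, 12))
            k = int(rng.integers(2, 6))
            X = rng.normal(size=(n, k)) + rng.normal(size=(1, k))
            res = rm_anova_oneway(X)
            ref = pingouin.rm_anova(
                data=_long_format(X), dv="y", within="level",
                subject="subject", correction=False)
            assert res.F == pytest.approx(ref["F"].iloc[0], abs=1e-8)
            assert res.p == pytest.approx(ref["p_unc"].iloc[0], abs=1e-6)
            assert res.df1 == ref["ddof1"].iloc[0]
            assert res.df2 == ref["ddof2"].iloc[0]

    def test_effect_monotonicity(self, rng):
        """Growing a constant post-onset effect never lowers F.

        Starting from a design with no level effect (columns centered),
        the level sum of squares is quadratic in the added shift while
        the error term is unchanged, so F must rise monotonically.
        """
        X = rng.normal(size=(10, 4))
        X -= X.mean(axis=0, keepdims=True)
        f_prev = rm_anova_oneway(X).F
        for shift in (0.5, 1.0, 2.0):
            Xs = X.copy()
            Xs[:, 1:] += shift
            f_new = rm_anova_oneway(Xs).F
            assert f_new >= f_prev
            f_prev = f_new

    def test_incomplete_design_rejected(self):
        X = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="incomplete"):
            rm_anova_oneway(X)


class TestDunnett:
    def test_levels_identical_to_control_give_p_one(self, rng):
        X = np.tile(rng.normal(size=(8, 1)), (1, 4))
        contrasts = dunnett_vs_control(X, control=0, seed=1)
        assert all(c.p_adjusted == pytest.approx(1.0, abs=0.01)
                   for c in contrasts)

    def test_single_contrast_equals_paired_t(self, rng):
        X = rng.normal(size=(9, 2))
        (c,) = dunnett_vs_control(X, control=0, seed=1)
        ref = paired_t(X[:, 1], X[:, 0])
        assert c.p_adjusted == pytest.approx(ref.p, abs=1e-12)
        assert c.t == pytest.approx(ref.t, abs=1e-12)

    @pytest.mark.parametrize("trial", range(5))
    def test_dominated_by_bonferroni(self, trial):
        """Dunnett-adjusted p never exceeds the Bonferroni-adjusted p."""
        rng = np.random.default_rng(100 + trial)
        X = rng.normal(size=(10, 4)) + np.array([0, 0.3, 0.6, 0.9])
        dun = dunnett_vs_control(X, control=0, seed=5, n_mc=50_000)
        bon = dunnett_vs_control(X, control=0, adjust="bonferroni")
        for cd, cb in zip(dun, bon):
            assert cd.p_adjusted <= cb.p_adjusted + 0.01

    def test_ci_contains_estimate(self, rng):
        X = rng.normal(size=(10, 4))
        for c in dunnett_vs_control(X, control=0, seed=2, n_mc=20_000):
            assert c.ci_low <= c.estimate <= c.ci_high

    def test_large_true_effect_detected(self, rng):
        X = rng.normal(size=(10, 4))
        X[:, 3] += 3.0
        contrasts = dunnett_vs_control(X, control=0, seed=3)
        assert contrasts[-1].p_adjusted < 0.01


class TestTwowayRM:
    def test_additive_data_gives_zero_interaction(self, rng):
        n, a, b = 8, 2, 3
        subj = rng.normal(size=(n, 1, 1))
        fa = rng.normal(size=(1, a, 1))
        fb = rng.normal(size=(1, 1, b))
        res = rm_anova_twoway_interaction(subj + fa + fb)
        assert res.F == pytest.approx(0.0, abs=1e-16)

    def test_2x2_equals_paired_t_on_difference_of_differences(self, rng):
        Y = rng.normal(size=(12, 2, 2))
        res = rm_anova_twoway_interaction(Y)
        dd = (Y[:, 1, 1] - Y[:, 1, 0]) - (Y[:, 0, 1] - Y[:, 0, 0])
        t = paired_t(dd, np.zeros_like(dd))
        assert res.F == pytest.approx(t.t**2, abs=1e-10)
        assert res.p == pytest.approx(t.p, abs=1e-10)

    def test_subject_order_invariance(self, rng):
        Y = rng.normal(size=(9, 2, 2))
        res1 = rm_anova_twoway_interaction(Y)
        res2 = rm_anova_twoway_interaction(Y[::-1])
        assert res1.F == pytest.approx(res2.F, abs=1e-12)

    def test_matches_reference_implementation(self, rng):
        for _ in range(10):
            n, a, b = int(rng.integers(4, 9)), 2, int(rng.integers(2, 4))
            Y = rng.normal(size=(n, a, b))
            res = rm_anova_twoway_interaction(Y)
            rows = []
            for i in range(n):
                for j in range(a):
                    for k in range(b):
                        rows.append({"subject": i, "A": f"a{j}",
                                     "B": f"b{k}", "y": Y[i, j, k]})
            ref = pingouin.rm_anova(data=pd.DataFrame(rows), dv="y",
                                    within=["A", "B"], subject="subject")
            inter = ref[ref["Source"] == "A * B"].iloc[0]
            assert res.F == pytest.approx(inter["F"], abs=1e-8)
            assert res.p == pytest.approx(inter["p_unc"], abs=1e-6)

    def test_incomplete_layout_rejected(self):
        Y = np.full((3, 2, 2), 1.0)
        Y[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="incomplete"):
            rm_anova_twoway_interaction(Y)


class TestUnpairedT:
    def test_identical_samples(self):
        res = unpaired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p == 1.0

    def test_hand_computed_example(self):
        # pooled SD = 1, SE = sqrt(2/3): t = -3/sqrt(2/3) = -3.674
        res = unpaired_t([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.t == pytest.approx(-3.674234614, abs=1e-8)
        assert res.df == 4

    def test_df_for_six_vs_six(self, rng):
        res = unpaired_t(rng.normal(size=6), rng.normal(size=6))
        assert res.df == 10

    def test_matches_reference_implementation(self, rng):
        for _ in range(50):
            a = rng.normal(size=int(rng.integers(2, 15)))
            b = rng.normal(1.0, 2.0, size=int(rng.integers(2, 15)))
            res = unpaired_t(a, b)
            ref = sps.ttest_ind(a, b, equal_var=True)
            assert res.t == pytest.approx(ref.statistic, abs=1e-8)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-6)
            lo, hi = ref.confidence_interval(0.95)
            assert res.ci_low == pytest.approx(lo, abs=1e-8)
            assert res.ci_high == pytest.approx(hi, abs=1e-8)

    def test_zero_variance_unequal_means_rejected(self):
        with pytest.raises(ValueError, match="zero pooled variance"):
            unpaired_t([1.0, 1.0], [2.0, 2.0])
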