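"""Rank-based inference layer: hand values, oracles and invariances."""

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

from pedprs import (
    chi_square_table,
    dunn_multiple,
    kruskal_wallis,
    partial_spearman,
    rank_interaction,
    rank_r_squared,
    spearman,
    trend_test,
    wilcoxon_ranksum,
)


class TestSpearman:
    def test_reversed_ranks(self):
        assert spearman([1, 2, 3], [3, 2, 1]).statistic == pytest.approx(-1.0)

    def test_identity(self):
        assert spearman([1, 2, 3, 4], [1, 2, 3, 4]).statistic == pytest.approx(1.0)

    def test_hand_values(self):
        # d² = (1,1,1,1,0): r_s = 1 - 6*4/120 = 0.8
        res = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.statistic == pytest.approx(0.8)
        assert res.df == 3
        # d² = (1,1,4,0,0): r_s = 1 - 6*6/120 = 0.7
        assert spearman([1, 2, 3, 4, 5], [2, 3, 1, 4, 5]).statistic == pytest.approx(0.7)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])


class TestPartialSpearman:
    def test_no_covariates_equals_spearman(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=30), rng.normal(size=30)
        plain = spearman(x, y)
        partial = partial_spearman(x, y, None)
        assert partial.statistic == pytest.approx(plain.statistic)
        assert partial.p_value == pytest.approx(plain.p_value)

    def test_shared_monotone_confounder_vanishes(self):
        z = np.linspace(0, 1, 40)
        x = np.exp(z)
        y = z**3 + 1
        res = partial_spearman(x, y, z)
        assert abs(res.statistic) < 1e-10

    def test_matches_pingouin_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(42)
        for _ in range(5):
            df = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("xyab"))
            ours = partial_spearman(df["x"], df["y"], df[["a", "b"]].to_numpy())
            ref = pingouin.partial_corr(
                df, x="x", y="y", covar=["a", "b"], method="spearman"
            )
            assert ours.statistic == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)

    def test_null_partial_correlation_small(self):
        rng = np.random.default_rng(1)
        n = 10000
        z = rng.normal(size=(n, 2))
        x = z @ [1.0, 0.5] + rng.normal(size=n)
        y = z @ [-0.5, 1.0] + rng.normal(size=n)
        res = partial_spearman(x, y, z)
        assert abs(res.statistic) < 0.05

    def test_requires_enough_df(self):
        with pytest.raises(ValueError):
            partial_spearman([1, 2, 3], [3, 1, 2], np.ones((3, 2)))


class TestWilcoxon:
    def test_exact_small_sample(self):
        res = wilcoxon_ranksum([1, 2], [3, 4])
        assert res.statistic == 3.0
        assert res.p_value == pytest.approx(1 / 3)

    def test_identical_groups_p_one(self):
        res = wilcoxon_ranksum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=30), rng.normal(0.5, 1, size=40)
        assert wilcoxon_ranksum(a, b).p_value == pytest.approx(
            wilcoxon_ranksum(np.exp(a), np.exp(b)).p_value
        )

    def test_matches_scipy_normal_approximation(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(3)
        a, b = rng.normal(size=50), rng.normal(0.3, 1, size=60)
        ours = wilcoxon_ranksum(a, b)
        ref = mannwhitneyu(a, b, method="asymptotic", use_continuity=False)
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-10)


class TestKruskalWallis:
    def test_hand_value(self):
        # (12/20)(2*1.5² + 2*3.5²) - 15 = 2.4
        res = kruskal_wallis([[1, 2], [3, 4]])
        assert res.statistic == pytest.approx(2.4)
        assert res.df == 1

    def test_identical_groups(self):
        res = kruskal_wallis([[5, 5], [5, 5, 5]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_two_groups_equals_squared_wilcoxon_z(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 10, size=40).astype(float)  # ties present
        b = rng.integers(2, 12, size=55).astype(float)
        H = kruskal_wallis([a, b]).statistic
        z = wilcoxon_ranksum(a, b).extra["z"]
        assert H == pytest.approx(z**2, rel=1e-10)


class TestDunn:
    def test_hand_value(self):
        res = dunn_multiple([[1, 2], [3, 4]])
        assert res[0].statistic == pytest.approx(-2 / np.sqrt(5 / 3))
        assert res[0].statistic == pytest.approx(-1.5492, abs=1e-4)

    def test_equal_mean_ranks(self):
        res = dunn_multiple([[1, 4], [2, 3]])
        assert res[0].statistic == pytest.approx(0.0)
        assert res[0].p_value == pytest.approx(1.0)

    def test_bonferroni_adjustment_caps_at_one(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(size=20) for _ in range(4)]
        res = dunn_multiple(groups, adjust="bonferroni")
        assert len(res) == 6
        for r in res:
            assert r.p_value == pytest.approx(min(1.0, 6 * r.extra["p_unadjusted"]))

    def test_holm_never_exceeds_bonferroni(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(loc=mu, size=15) for mu in (0, 0.2, 0.8)]
        bonf = dunn_multiple(groups, adjust="bonferroni")
        holm = dunn_multiple(groups, adjust="holm")
        for b, h in zip(bonf, holm):
            assert h.p_value <= b.p_value + 1e-12

    def test_familywise_error_conservative(self):
        rng = np.random.default_rng(7)
        reps, fwe = 2000, 0
        for _ in range(reps):
            groups = [rng.normal(size=n) for n in (20, 50, 30)]
            res = dunn_multiple(groups)
            fwe += any(r.p_value < 0.05 for r in res)
        assert fwe / reps <= 0.05

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            dunn_multiple([[1, 2], []])


def _jt_brute_force(groups):
    """Enumerate all distinct assignments of pooled values to group slots."""
    from pedprs.stats import _jt_statistic

    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    sizes = [len(g) for g in groups]
    stats = []

    def recurse(remaining, assigned):
        if len(assigned) == len(sizes) - 1:
            stats.append(_jt_statistic(assigned + [pooled[remaining]]))
            return
        for comb in itertools.combinations(remaining, sizes[len(assigned)]):
            rest = [r for r in remaining if r not in comb]
            recurse(rest, assigned + [pooled[list(comb)]])

    recurse(list(range(len(pooled))), [])
    return np.asarray(stats)


class TestTrend:
    def test_perfect_ordering_attains_maximum(self):
        res = trend_test([[1, 2], [3, 4], [5, 6]])
        assert res.statistic == 12.0

    def test_identical_multisets_at_midpoint(self):
        res = trend_test([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])
        assert res.statistic == pytest.approx(res.extra["expected"])
        assert res.p_value == pytest.approx(1.0)

    def test_exact_p_matches_enumeration(self):
        groups = [[1, 3], [2, 4], [5, 6]]
        res = trend_test(groups)
        dist = _jt_brute_force(groups)
        assert len(dist) == 90
        jt = res.statistic
        lo = np.mean(dist <= jt + 1e-12)
        hi = np.mean(dist >= jt - 1e-12)
        assert res.p_value == pytest.approx(min(1.0, 2 * min(lo, hi)))

    def test_two_groups_guarded(self):
        with pytest.raises(ValueError, match="wilcoxon"):
            trend_test([[1, 2], [3, 4]])

    def test_normal_approximation_detects_planted_trend(self):
        rng = np.random.default_rng(8)
        groups = [rng.normal(loc=mu, size=80) for mu in (0.0, 0.25, 0.5)]
        res = trend_test(groups)
        assert res.p_value < 0.001
        assert res.statistic > res.extra["expected"]


class TestInteraction:
    def test_constant_outcome(self):
        res = rank_interaction([1.0] * 12, ["a", "b"] * 6, ["x"] * 6 + ["y"] * 6)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_planted_crossover_detected(self):
        rng = np.random.default_rng(9)
        n = 400
        fa = rng.choice(["lo", "hi"], size=n)
        fb = rng.choice(["u", "v"], size=n)
        effect = np.where((fa == "hi") == (fb == "v"), 1.0, -1.0)
        y = effect + rng.normal(size=n)
        res = rank_interaction(y, fa, fb)
        assert res.p_value < 0.001

    def test_matches_statsmodels_type2_ss(self):
        sm = pytest.importorskip("statsmodels.api")
        import pandas as pd
        from statsmodels.formula.api import ols
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(10)
        n = 120
        df = pd.DataFrame(
            {
                "y": rng.normal(size=n),
                "a": rng.choice(["a1", "a2", "a3"], size=n),
                "b": rng.choice(["b1", "b2"], size=n),
            }
        )
        ours = rank_interaction(df["y"], df["a"], df["b"])
        df["r"] = rankdata(df["y"])
        fit = ols("r ~ C(a) * C(b)", data=df).fit()
        tab = anova_lm(fit, typ=2)
        ss_int = float(tab.loc["C(a):C(b)", "sum_sq"])
        ms_total = float(((df["r"] - df["r"].mean()) ** 2).sum() / (n - 1))
        assert ours.statistic == pytest.approx(ss_int / ms_total, rel=1e-8)

    def test_empty_cell_raises(self):
        with pytest.raises(ValueError, match="cell"):
            rank_interaction([1, 2, 3], ["a", "a", "b"], ["x", "y", "x"])


class TestChiSquare:
    def test_homogeneous_table(self):
        res = chi_square_table([[10, 10], [10, 10]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_perfect_separation(self):
        res = chi_square_table([[20, 0], [0, 20]])
        assert res.statistic == pytest.approx(40.0)
        assert res.df == 1

    def test_statistic_scales_with_counts(self):
        t = np.array([[12, 6], [8, 14]])
        s1 = chi_square_table(t).statistic
        s3 = chi_square_table(3 * t).statistic
        assert s3 == pytest.approx(3 * s1)

    def test_zero_marginal_dropped(self):
        with pytest.warns(UserWarning, match="zero-marginal"):
            res = chi_square_table([[5, 0, 5], [5, 0, 5]])
        assert res.df == 1

    def test_small_cells_warn(self):
        with pytest.warns(UserWarning, match="below 5"):
            chi_square_table([[2, 3], [3, 2]])


class TestRankRSquared:
    def test_monotone_pair(self):
        x = np.arange(10.0)
        assert rank_r_squared(x, np.exp(x)) == pytest.approx(1.0)

    def test_equals_squared_spearman(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=100), rng.normal(size=100)
        assert rank_r_squared(x, y) == pytest.approx(spearman(x, y).statistic ** 2)

    def test_independent_pair_near_zero(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=10000), rng.normal(size=10000)
        assert rank_r_squared(x, y) < 0.002


def test_rank_tests_invariant_under_monotone_transforms():
    rng = np.random.default_rng(13)
    a, b, c = (rng.normal(loc=m, size=25) for m in (0, 0.3, 0.6))
    raw = [a, b, c]
    warped = [np.exp(a), np.exp(b), np.exp(c)]
    assert kruskal_wallis(raw).p_value == pytest.approx(kruskal_wallis(warped).p_value)
    assert trend_test(raw).p_value == pytest.approx(trend_test(warped).p_value)
    for r1, r2 in zip(dunn_multiple(raw), dunn_multiple(warped)):
        assert r1.statistic == pytest.approx(r2.statistic)
    assert spearman(a, b).statistic == pytest.approx(spearman(np.exp(a), np.exp(b)).statistic)
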