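import itertools

import numpy as np
import pytest
from scipy import stats

from microleak.univariate_stats import (ContingencyTable, anova_oneway,
                                        bonferroni_alpha, chi_square_2x2,
                                        classifier_metrics, fisher_exact_2x2,
                                        freeman_halton_exact, kruskal_wallis,
                                        posthoc_pairwise,
                                        select_categorical_test, spearman)


class TestAnova:
    def test_identical_groups(self):
        res = anova_oneway([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_f(self):
        # SSB = 13.5, SSW = 4 -> F = 13.5 on df (1, 4)
        res = anova_oneway([[1, 2, 3], [4, 5, 6]])
        assert res.statistic == pytest.approx(13.5)
        assert res.df == (1, 4)
        assert res.p_value == pytest.approx(0.0213, abs=1e-3)

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([[1.0], [2.0, 3.0]])

    def test_equal_means_unequal_variances_f_near_one(self):
        # under H0 the F statistic has mean df2/(df2-2); with many sims the
        # average should hover there rather than explode
        rng = np.random.default_rng(0)
        fs = []
        for _ in range(300):
            a = rng.normal(0, 1, 20)
            b = rng.normal(0, 3, 20)
            fs.append(anova_oneway([a, b]).statistic)
        assert np.mean(fs) < 3.0


class TestKruskalWallis:
    def test_identical_groups(self):
        res = kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_hand_ranked_example(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert res.statistic == pytest.approx(3.857, abs=1e-3)
        assert res.p_value == pytest.approx(0.0495, abs=1e-3)

    def test_tie_corrected_formula_oracle(self):
        rng = np.random.default_rng(3)
        groups = [rng.integers(0, 4, 8).astype(float) for _ in range(3)]
        pooled = np.concatenate(groups)
        ranks = stats.rankdata(pooled)
        n = pooled.size
        idx = np.cumsum([0] + [g.size for g in groups])
        h = 12 / (n * (n + 1)) * sum(
            ranks[a:b].sum() ** 2 / (b - a) for a, b in zip(idx, idx[1:])
        ) - 3 * (n + 1)
        _, counts = np.unique(pooled, return_counts=True)
        h /= 1 - ((counts ** 3 - counts).sum()) / (n ** 3 - n)
        assert kruskal_wallis(groups).statistic == pytest.approx(h)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(size=6), rng.normal(1, 1, 7)]
        h1 = kruskal_wallis(groups).statistic
        h2 = kruskal_wallis([np.exp(g) for g in groups]).statistic
        assert h1 == pytest.approx(h2)


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).statistic == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [8, 6, 4, 2]).statistic == pytest.approx(-1.0)

    def test_ties_match_pearson_on_midranks(self):
        x = [1, 2, 2, 3, 5, 5, 5]
        y = [2, 1, 4, 4, 7, 6, 6]
        rho = spearman(x, y).statistic
        oracle = stats.pearsonr(stats.rankdata(x), stats.rankdata(y)).statistic
        assert rho == pytest.approx(oracle)

    def test_constant_vector_flagged(self):
        res = spearman([1, 1, 1], [1, 2, 3])
        assert np.isnan(res.statistic) and "constant" in res.note


class TestPosthoc:
    def test_identical_groups_share_a_letter(self):
        for method in ("tukey", "dunn", "duncan"):
            res = posthoc_pairwise([[5, 5, 5]] * 3, method=method)
            assert all(v == "a" for v in res.letters.values())
            vals = res.p_values.to_numpy()
            assert np.all(vals[~np.isnan(vals)] >= 0.999)

    @pytest.mark.parametrize("method", ["tukey", "dunn", "duncan"])
    def test_shifted_group_gets_distinct_letter(self, method):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0, 1, 12)
        c = rng.normal(8, 1, 12)
        res = posthoc_pairwise([a, b, c], method=method, labels=["a", "b", "c"])
        assert res.letters["c"] not in (res.letters["a"], res.letters["b"])
        assert set(res.letters["a"]) & set(res.letters["b"])

    def test_tukey_matches_studentized_range_oracle(self):
        groups = [np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])]
        res = posthoc_pairwise(groups, method="tukey")
        k, n = 2, 6
        msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / (n - k)
        q = abs(groups[0].mean() - groups[1].mean()) / np.sqrt(msw / 3)
        oracle = stats.studentized_range.sf(q, k, n - k)
        assert res.p_values.iloc[0, 1] == pytest.approx(oracle, abs=1e-6)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            posthoc_pairwise([[1, 2], [3, 4]], method="scheffe")


class TestChiSquare:
    def test_leak_rate_comparison(self):
        res = chi_square_2x2([[9, 6], [10, 5]])
        assert res.p_value == pytest.approx(0.705, abs=1e-3)
        assert res.df == 1

    def test_proportional_table_is_null(self):
        res = chi_square_2x2([[2, 4], [3, 6]])  # ad == bc
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_textbook_formula_on_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            t = rng.integers(1, 30, (2, 2))
            a, b, c, d = t.flat
            n = t.sum()
            expected = n * (a * d - b * c) ** 2 / (
                (a + b) * (c + d) * (a + c) * (b + d))
            assert chi_square_2x2(t).statistic == pytest.approx(expected)

    def test_invariant_under_row_and_column_swaps(self):
        t = np.array([[9, 6], [10, 5]])
        p = chi_square_2x2(t).p_value
        assert chi_square_2x2(t[::-1]).p_value == pytest.approx(p)
        assert chi_square_2x2(t[:, ::-1]).p_value == pytest.approx(p)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 5], [0, 3]])


class TestFisherExact:
    def test_protective_fmt_comparison(self):
        assert fisher_exact_2x2([[10, 5], [13, 0]]).p_value == pytest.approx(0.044, abs=5e-4)

    def test_wd_slurry_comparison(self):
        assert fisher_exact_2x2([[9, 6], [12, 4]]).p_value == pytest.approx(0.46, abs=5e-3)

    def test_zero_outcome_column_gives_p_one(self):
        assert fisher_exact_2x2([[3, 0], [5, 0]]).p_value == pytest.approx(1.0)

    def test_conservative_under_hypergeometric_null(self):
        # fixed margins (12, 8) x (10, 10): exact test rejects at <= alpha
        rng = np.random.default_rng(9)
        r1, n, c1 = 12, 20, 10
        draws = rng.hypergeometric(c1, n - c1, r1, size=10_000)
        pvals = {}
        for a in np.unique(draws):
            t = [[a, r1 - a], [c1 - a, n - r1 - c1 + a]]
            pvals[a] = fisher_exact_2x2(t).p_value
        ps = np.array([pvals[a] for a in draws])
        for alpha in (0.01, 0.05):
            assert (ps <= alpha).mean() <= alpha + 0.003


class TestFreemanHalton:
    def test_survival_table(self):
        res = freeman_halton_exact([[15, 1], [15, 1], [16, 0], [13, 3]])
        assert res.p_value == pytest.approx(0.38, abs=5e-3)

    def test_reduces_to_fisher_for_2x2(self):
        for t in ([[10, 5], [13, 0]], [[9, 6], [12, 4]], [[3, 7], [6, 1]]):
            assert freeman_halton_exact(t).p_value == pytest.approx(
                fisher_exact_2x2(t).p_value, rel=1e-9)

    def test_identical_rows_give_p_one(self):
        assert freeman_halton_exact([[8, 2]] * 4).p_value == pytest.approx(1.0)

    def test_enumeration_bound_enforced(self):
        big = [[100, 100], [100, 100]]
        with pytest.raises(ValueError, match="Monte-Carlo"):
            freeman_halton_exact(big)


class TestSelectionRule:
    @pytest.mark.parametrize("table,expected", [
        ([[9, 6], [10, 5]], "chi_square"),
        ([[10, 5], [13, 0]], "fisher"),
        ([[50, 50], [60, 40]], "chi_square"),
        ([[15, 1], [15, 1], [16, 0], [13, 3]], "freeman_halton"),
    ])
    def test_small_cell_rule(self, table, expected):
        assert select_categorical_test(table) == expected


class TestBonferroni:
    def test_thresholds(self):
        assert bonferroni_alpha(0.05, 3) == pytest.approx(0.0167, abs=5e-4)
        assert bonferroni_alpha(0.05, 10) == pytest.approx(0.005)
        assert bonferroni_alpha(0.05, 1) == 0.05

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestClassifierMetrics:
    def test_arithmetic(self):
        m = classifier_metrics(tp=8, fp=3, tn=7, fn=2)
        assert m.sensitivity == pytest.approx(0.8)
        assert m.specificity == pytest.approx(0.7)
        assert m.accuracy == pytest.approx(0.75)

    def test_perfect_and_degenerate_predictors(self):
        perfect = classifier_metrics(tp=5, fp=0, tn=5, fn=0)
        assert (perfect.accuracy, perfect.sensitivity, perfect.specificity) == (1, 1, 1)
        all_neg = classifier_metrics(tp=0, fp=0, tn=5, fn=5)
        assert all_neg.sensitivity == 0 and all_neg.specificity == 1
        assert all_neg.accuracy == pytest.approx(0.5)

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError):
            classifier_metrics(tp=0, fp=1, tn=3, fn=0)
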