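import numpy as np
import pytest
from scipy import stats as sps

import tendrilkin as tk
from tendrilkin.errors import ContractError, InsufficientDataError


def _hand_kruskal_h(groups):
    """Independent oracle: tie-corrected H from first principles."""
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    n_total = len(pooled)
    offset, h = 0, 0.0
    for g in groups:
        r = ranks[offset : offset + len(g)]
        h += len(g) * (r.mean() - (n_total + 1) / 2) ** 2
        offset += len(g)
    h *= 12.0 / (n_total * (n_total + 1))
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n_total**3 - n_total)
    return h / correction


def _mann_whitney_u(x, y):
    """Brute-force U: count of (x_i, y_j) pairs with x_i > y_j (+ half-ties)."""
    u = 0.0
    for xi in x:
        for yj in y:
            u += 1.0 if xi > yj else (0.5 if xi == yj else 0.0)
    return u


class TestGroupSummary:
    def test_linear_interpolation_percentiles(self):
        s = tk.summarize_group([1, 2, 3, 4], "AC")
        assert (s.median, s.p25, s.p75) == (2.5, 1.75, 3.25)
        assert s.iqr == pytest.approx(1.5)

    def test_constant_values(self):
        s = tk.summarize_group([7.0, 7.0, 7.0, 7.0], "BC")
        assert s.sd == 0.0 and s.iqr == 0.0
        assert np.isnan(s.shapiro_p)

    def test_minimum_group_size(self):
        with pytest.raises(InsufficientDataError):
            tk.summarize_group([1.0, 2.0], "AC")

    def test_recovers_generator_moments(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(48.0, 13.0, 2000)
        s = tk.summarize_group(vals, "BC")
        assert s.mean == pytest.approx(48.0, abs=1.0)
        assert s.sd == pytest.approx(13.0, abs=1.0)


class TestKruskalWallis:
    def test_identical_groups_give_zero(self):
        res = tk.kruskal_wallis([np.ones(5), np.ones(4), np.ones(6)])
        assert res.statistic == 0.0 and res.p == 1.0 and res.df == 2

    def test_hand_rank_example(self):
        res = tk.kruskal_wallis([np.array([1.0, 2.0]), np.array([3.0, 4.0])])
        assert res.statistic == pytest.approx(2.4)
        assert res.df == 1

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_first_principles_formula_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.integers(0, 6, rng.integers(4, 10)).astype(float)
                  for _ in range(3)]
        res = tk.kruskal_wallis(groups)
        assert res.statistic == pytest.approx(_hand_kruskal_h(groups), rel=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(0, 1, 8) for _ in range(3)]
        h1 = tk.kruskal_wallis(groups).statistic
        h2 = tk.kruskal_wallis([np.exp(g) for g in groups]).statistic
        assert h1 == pytest.approx(h2, rel=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_two_group_h_is_monotone_in_mann_whitney_u(self, seed):
        """With 2 groups and no ties, H is a strictly increasing function of
        |U - n1*n2/2|, checked against the brute-force pairwise-count U."""
        rng = np.random.default_rng(100 + seed)
        pairs = []
        for _ in range(6):
            x, y = rng.normal(0, 1, 6), rng.normal(0.5, 1, 7)
            u_dev = abs(_mann_whitney_u(x, y) - len(x) * len(y) / 2)
            pairs.append((u_dev, tk.kruskal_wallis([x, y]).statistic))
        pairs.sort()
        devs, hs = zip(*pairs)
        for (d1, h1), (d2, h2) in zip(pairs, pairs[1:]):
            assert (h2 - h1) * (d2 - d1) >= -1e-12

    def test_needs_two_nonempty_groups(self):
        with pytest.raises(ContractError):
            tk.kruskal_wallis([np.ones(3)])


class TestStudentT:
    def test_reference_group_summaries(self):
        """Frozen check against published group summaries (n = 8 each):
        higher AC submovement counts give t ~ -2.22 and d ~ -1.11."""
        res = tk.student_t_pooled(8, 48.000, 13.148, 8, 67.125, 20.490)
        assert res.statistic == pytest.approx(-2.2219040909, rel=1e-9)
        assert res.df == 14
        assert res.effect_size == pytest.approx(-1.1109520455, rel=1e-9)

    def test_equal_groups_give_zero(self):
        res = tk.student_t_pooled(8, 5.0, 2.0, 8, 5.0, 2.0)
        assert res.statistic == 0.0 and res.effect_size == 0.0
        assert res.p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_raw_and_summary_paths_agree(self, seed):
        rng = np.random.default_rng(seed)
        x1, x2 = rng.normal(0, 1, 8), rng.normal(0.7, 1.3, 9)
        raw = tk.student_t_from_samples(x1, x2)
        summ = tk.student_t_pooled(
            len(x1), float(np.mean(x1)), float(np.std(x1, ddof=1)),
            len(x2), float(np.mean(x2)), float(np.std(x2, ddof=1)),
        )
        assert raw.statistic == pytest.approx(summ.statistic, rel=1e-12)
        assert raw.effect_size == pytest.approx(summ.effect_size, rel=1e-12)
        # independent oracle for the whole path
        ref = sps.ttest_ind(x1, x2, equal_var=True)
        assert raw.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert raw.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ContractError):
            tk.student_t_pooled(8, 5.0, 0.0, 8, 5.0, 0.0)
        with pytest.raises(ContractError):
            tk.student_t_pooled(1, 5.0, 1.0, 8, 5.0, 1.0)

    def test_effect_ci_brackets_d(self):
        res = tk.student_t_pooled(8, 115.5, 23.513, 8, 169.75, 63.209)
        assert res.effect_ci_low < res.effect_size < res.effect_ci_high


class TestPosthoc:
    def test_identical_groups_all_nonsignificant(self):
        groups = [np.ones(6)] * 3
        for method in ("tukey_hsd", "dunn_bonferroni"):
            for res in tk.pairwise_posthoc(groups, ("A", "B", "C"), method=method):
                assert res.p == pytest.approx(1.0)

    @pytest.mark.parametrize("method,n", [("tukey_hsd", 8), ("dunn_bonferroni", 12)])
    def test_well_separated_groups_all_significant(self, method, n):
        """Cleanly separated groups come out significant on every pair. The
        rank-based Dunn test needs n = 12: with 8 per group even maximal rank
        separation of adjacent groups gives z ~ 2.26, Bonferroni p ~ 0.07."""
        rng = np.random.default_rng(21)
        groups = [rng.normal(mu, 1.0, n) for mu in (0.0, 5.0, 10.0)]
        results = tk.pairwise_posthoc(groups, ("a", "b", "c"), method=method)
        assert len(results) == 3
        assert all(r.p < 0.05 for r in results)

    def test_bonferroni_adjustment_never_decreases_p(self):
        rng = np.random.default_rng(22)
        groups = [rng.normal(0, 1, 8) for _ in range(3)]
        adjusted = tk.pairwise_posthoc(groups, ("a", "b", "c"), method="dunn_bonferroni")
        pooled = np.concatenate(groups)
        ranks = sps.rankdata(pooled)
        for res in adjusted:
            assert 0.0 <= res.p <= 1.0
        # raw two-group Dunn z recomputed without the family factor
        raw = tk.pairwise_posthoc(groups, ("a", "b", "c"), method="dunn_bonferroni")
        for r in raw:
            unadjusted = 2 * sps.norm.sf(abs(r.statistic))
            assert r.p >= unadjusted - 1e-12

    def test_family_needs_three_groups(self):
        with pytest.raises(ContractError):
            tk.pairwise_posthoc([np.ones(4), np.ones(4)], ("a", "b"))


class TestNormality:
    def test_contract_ranges(self):
        rng = np.random.default_rng(1)
        w, p = tk.normality_test(rng.normal(0, 1, 20))
        assert 0 < w <= 1 and 0 <= p <= 1

    def test_outlier_drives_p_down(self):
        vals = np.concatenate([np.full(10, 5.0) + np.linspace(0, 1e-3, 10), [50.0]])
        _, p = tk.normality_test(vals)
        assert p < 0.01

    def test_type_i_error_rate_near_alpha(self):
        """With normal data, Shapiro-Wilk rejects ~5% of the time at alpha 0.05."""
        rng = np.random.default_rng(7)
        rejections = sum(
            tk.normality_test(rng.normal(0, 1, 8))[1] < 0.05 for _ in range(1000)
        )
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_sample_size_bounds(self):
        with pytest.raises(ContractError):
            tk.normality_test([1.0, 2.0])
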