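"""Group-comparison statistics: t, chi-square, correlation, ANOVA,
Games-Howell."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sbmorph import (
    CohortConfig,
    SummaryGroup,
    anova_oneway,
    chi_square,
    correlation_table,
    games_howell,
    generate_cohort,
    ttest_from_summary,
    ttest_raw,
)


def _sample_with_moments(mean, sd, n, seed=0):
    """Affine-rescale a draw so its sample mean/SD are exact."""
    x = np.random.default_rng(seed).normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return x * sd + mean


class TestTTest:
    def test_reference_age_row(self):
        res = ttest_from_summary(SummaryGroup(72.38, 9.09, 45),
                                 SummaryGroup(67.71, 9.78, 73))
        assert res.statistic == pytest.approx(2.58, abs=0.01)
        assert res.p == pytest.approx(0.011, abs=0.001)
        assert res.df == 116

    def test_reference_education_row(self):
        res = ttest_from_summary(SummaryGroup(14.47, 1.85, 45),
                                 SummaryGroup(14.73, 2.29, 73))
        assert res.statistic == pytest.approx(-0.64, abs=0.01)

    def test_identical_groups(self):
        res = ttest_from_summary(SummaryGroup(5.0, 1.0, 10),
                                 SummaryGroup(5.0, 1.0, 10))
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0)

    def test_raw_equals_summary_exactly(self, rng):
        x1 = rng.normal(0, 1, 23)
        x2 = rng.normal(0.5, 2, 31)
        raw = ttest_raw(x1, x2)
        summ = ttest_from_summary(SummaryGroup.of(x1), SummaryGroup.of(x2))
        assert raw.statistic == summ.statistic
        assert raw.p == summ.p

    def test_constructed_samples_reproduce_summary_t(self):
        x1 = _sample_with_moments(72.38, 9.09, 45, seed=1)
        x2 = _sample_with_moments(67.71, 9.78, 73, seed=2)
        res = ttest_raw(x1, x2)
        assert res.statistic == pytest.approx(2.58, abs=0.01)

    def test_shift_sign_matches_t_sign(self, rng):
        x = rng.normal(0, 1, 200)
        assert ttest_raw(x + 1.0, x).statistic > 0
        assert ttest_raw(x - 1.0, x).statistic < 0

    def test_welch_option_differs_under_heteroscedasticity(self):
        g1, g2 = SummaryGroup(72.38, 9.09, 45), SummaryGroup(67.71, 9.78, 73)
        pooled = ttest_from_summary(g1, g2, equal_var=True)
        welch = ttest_from_summary(g1, g2, equal_var=False)
        assert welch.statistic != pooled.statistic
        assert welch.df < pooled.df

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError):
            ttest_raw([1.0], [2.0, 3.0])


class TestChiSquare:
    def test_uniform_table_is_null(self):
        res = chi_square([[10, 10], [10, 10]])
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # expected counts all 15; sum (o-e)^2/e = 4 * 25/15
        res = chi_square([[20, 10], [10, 20]])
        assert res.statistic == pytest.approx(6.667, abs=5e-4)
        assert res.df == 1

    def test_zero_margin_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero-margin"):
            res = chi_square([[5, 0, 5], [5, 0, 5]])
        assert res.df == 1  # one column removed

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            chi_square([[0, 0], [0, 0]])

    def test_permutation_invariance(self, rng):
        table = rng.integers(1, 30, (3, 4))
        base = chi_square(table)
        shuffled = chi_square(table[::-1][:, ::-1])
        assert shuffled.statistic == pytest.approx(base.statistic)


class TestCorrelationTable:
    def _table(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "subject_id": [str(i) for i in range(n)],
            "ab_label": rng.choice(["positive", "negative"], n),
            "sex": rng.choice(["M", "F"], n),
            "age": rng.normal(70, 8, n),
            "MMSE": rng.normal(25, 4, n),
        })

    def test_perfect_correlation_detected(self):
        tab = self._table()
        loadings = np.column_stack([tab["age"], -tab["age"].to_numpy()])
        out = correlation_table(loadings, tab, variables=["age", "MMSE"])
        assert out.loc["age", ("IC_1", "r")] == pytest.approx(1.0)
        assert out.loc["age", ("IC_2", "r")] == pytest.approx(-1.0)
        assert out.loc["age", ("IC_1", "p")] < 1e-10

    def test_bonferroni_never_more_permissive(self):
        tab = self._table(seed=2)
        loadings = np.random.default_rng(3).normal(size=(30, 2))
        out = correlation_table(loadings, tab)
        for comp in ("IC_1", "IC_2"):
            p = out[(comp, "p")].dropna()
            padj = out[(comp, "p_bonferroni")].dropna()
            assert (padj >= p - 1e-15).all()

    def test_zero_variance_variable_is_nan(self):
        tab = self._table()
        tab["MMSE"] = 25.0
        loadings = np.random.default_rng(1).normal(size=(30, 1))
        out = correlation_table(loadings, tab, variables=["MMSE"])
        assert np.isnan(out.loc["MMSE", ("IC_1", "r")])

    def test_planted_discriminative_loading_hits_target_band(self):
        # generator calibrated so r(disc loading, Ab) ~ -0.5 in the population
        cfg = CohortConfig(n_subjects=500, grid_shape=(12, 14, 12),
                           source_extent=2.0, n_sources=2, seed=13)
        _, table, truth = generate_cohort(cfg)
        out = correlation_table(truth.loadings, table,
                                variables=["ab_positivity"])
        r = out.loc["ab_positivity", ("IC_1", "r")]
        assert -0.6 < r < -0.4

    def test_affine_rescaling_flips_sign_with_slope(self):
        tab = self._table(seed=5)
        x = tab["age"].to_numpy()
        base = correlation_table(x[:, None], tab, variables=["MMSE"])
        flipped = correlation_table((-2.0 * x + 7.0)[:, None], tab,
                                    variables=["MMSE"])
        assert flipped.loc["MMSE", ("IC_1", "r")] == pytest.approx(
            -base.loc["MMSE", ("IC_1", "r")]
        )


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        g = [1.0, 2.0, 3.0]
        res = anova_oneway([g, g, g])
        assert res.statistic == pytest.approx(0.0)

    def test_two_group_f_equals_t_squared(self, rng):
        x1 = rng.normal(0, 1, 20)
        x2 = rng.normal(0.8, 1, 25)
        f = anova_oneway([x1, x2])
        t = ttest_raw(x1, x2)
        assert f.statistic == pytest.approx(t.statistic**2, rel=1e-10)
        assert f.p == pytest.approx(t.p, rel=1e-10)

    def test_extreme_shift_is_significant(self, rng):
        groups = [rng.normal(0, 1, 30), rng.normal(0, 1, 30),
                  rng.normal(10, 1, 30)]
        assert anova_oneway(groups).p < 1e-3

    def test_degrees_of_freedom(self, rng):
        groups = [rng.normal(size=5), rng.normal(size=6), rng.normal(size=7)]
        res = anova_oneway(groups)
        assert res.df == (2.0, 15.0)


class TestGamesHowell:
    def test_two_groups_reduce_to_welch(self, rng):
        x1 = rng.normal(0, 1, 20)
        x2 = rng.normal(1, 2, 35)
        (gh,) = games_howell([x1, x2])
        welch = ttest_raw(x1, x2, equal_var=False)
        assert gh.p == pytest.approx(welch.p, abs=1e-4)
        assert gh.statistic == pytest.approx(abs(welch.statistic) * np.sqrt(2),
                                             rel=1e-10)

    def test_identical_groups_not_significant(self):
        g = list(np.arange(10.0))
        results = games_howell([g, g, g])
        assert all(r.p > 0.99 for r in results)

    def test_shifted_group_detected(self, rng):
        base_sd = 1.0
        g1 = rng.normal(0, base_sd, 30)
        g2 = rng.normal(0, base_sd, 30)
        g3 = rng.normal(5 * base_sd, base_sd, 30)
        r12, r13, r23 = games_howell([g1, g2, g3])
        assert r13.p < 1e-3 and r23.p < 1e-3
        assert r12.p > 0.05

    def test_relabeling_invariance(self, rng):
        groups = [rng.normal(m, 1, 15) for m in (0, 1, 2)]
        fwd = games_howell(groups)
        rev = games_howell(groups[::-1])
        assert sorted(r.p for r in fwd) == pytest.approx(
            sorted(r.p for r in rev)
        )

    def test_p_monotone_in_mean_difference(self):
        # fixed variances and n; growing separation must not raise p
        ps = []
        for delta in (0.2, 0.5, 1.0, 2.0):
            g1 = _sample_with_moments(0.0, 1.0, 20, seed=1)
            g2 = _sample_with_moments(delta, 1.5, 25, seed=2)
            (res,) = games_howell([g1, g2])
            ps.append(res.p)
        assert all(b <= a + 1e-12 for a, b in zip(ps, ps[1:]))

    def test_zero_variance_pair_is_nan(self):
        g1 = [2.0, 2.0, 2.0]
        g2 = [3.0, 3.0, 3.0]
        (res,) = games_howell([g1, g2])
        assert np.isnan(res.p)

    def test_matches_pingouin_reference(self, rng):
        pingouin = pytest.importorskip("pingouin")
        vals = np.concatenate([
            rng.normal(0, 1, 18), rng.normal(0.7, 2, 22),
            rng.normal(1.5, 0.5, 15),
        ])
        labels = np.repeat(["a", "b", "c"], [18, 22, 15])
        df = pd.DataFrame({"y": vals, "g": labels})
        ref = pingouin.pairwise_gameshowell(data=df, dv="y", between="g")
        ours = games_howell(
            [vals[labels == g] for g in ("a", "b", "c")],
            labels=["a", "b", "c"],
        )
        ref_p = ref.sort_values(["A", "B"])["pval"].to_numpy()
        our_p = np.array([r.p for r in ours])
        np.testing.assert_allclose(our_p, ref_p, atol=1e-6)
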