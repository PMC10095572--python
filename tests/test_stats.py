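"""Inferential layer: normality screen, t tests, GLM, Duncan, correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from alphaerd.stats import (
    DegenerateDataError,
    SummaryGroup,
    duncan_posthoc,
    glm_genotype_effect,
    one_sample_erd_test,
    pearson_age_correlation,
    proportion_test,
    shapiro_wilk_screen,
    summary_two_sample_test,
)


def _cohort_frame(rng, n_cc=24, n_ct=48, effect=0.0, noise=10.0):
    n = n_cc + n_ct
    grp = np.array(["CC"] * n_cc + ["CT&TT"] * n_ct)
    age = rng.integers(30, 81, n)
    return pd.DataFrame(
        {
            "clu_group": grp,
            "apoe_group": rng.choice(["E4+", "E4-"], n),
            "sex": rng.choice(["m", "f"], n),
            "age": age,
            "erd_percent": rng.normal(0.0, noise, n) + np.where(grp == "CC", effect, 0.0),
        }
    )


class TestShapiroScreen:
    def test_calibration_on_normal_data(self):
        rng = np.random.default_rng(1)
        hits = sum(
            shapiro_wilk_screen(rng.normal(size=50))[1] > 0.05 for _ in range(100)
        )
        assert hits >= 90

    def test_power_on_lognormal(self):
        rng = np.random.default_rng(2)
        with pytest.warns(UserWarning, match="Shapiro"):
            hits = sum(
                shapiro_wilk_screen(rng.lognormal(0.0, 1.0, 100))[1] < 0.05
                for _ in range(100)
            )
        assert hits >= 90

    def test_constant_vector_degenerate(self):
        with pytest.raises(DegenerateDataError):
            shapiro_wilk_screen(np.full(20, 3.0))

    @pytest.mark.parametrize("n", [2, 5001])
    def test_n_out_of_range(self, n):
        with pytest.raises(ValueError, match="3 <= n"):
            shapiro_wilk_screen(np.zeros(n))


class TestOneSample:
    def test_symmetric_zero_mean(self):
        vals = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        t, df, p = one_sample_erd_test(vals)
        assert t == 0.0 and df == 4 and p == pytest.approx(1.0)

    def test_large_effect(self):
        rng = np.random.default_rng(3)
        vals = -5.0 + rng.normal(0.0, 0.01, 30)
        _, df, p = one_sample_erd_test(vals)
        assert df == 29 and p < 1e-6

    def test_zero_variance(self):
        with pytest.raises(DegenerateDataError):
            one_sample_erd_test(np.full(10, -5.0))

    def test_wilcoxon_variant_agrees_on_large_shift(self):
        rng = np.random.default_rng(12)
        vals = -8.0 + rng.normal(0.0, 1.0, 30)
        _, _, p_t = one_sample_erd_test(vals)
        _, _, p_w = one_sample_erd_test(vals, method="wilcoxon")
        assert p_t < 0.001 and p_w < 0.001

    def test_holm_adjustment_monotone_and_bounded(self):
        from alphaerd.stats import holm_adjust

        p = np.array([0.01, 0.04, 0.03, 0.5])
        adj = holm_adjust(p)
        assert np.all(adj >= p) and np.all(adj <= 1.0)
        assert adj[0] == pytest.approx(0.04)  # 0.01 × 4 (smallest of m=4)


class TestGLM:
    def test_df_den_is_n_minus_5(self):
        res = glm_genotype_effect(_cohort_frame(np.random.default_rng(4)))
        assert res.df_num == 1 and res.df_den == 72 - 5 and res.n == 72

    def test_detects_large_effect(self):
        res = glm_genotype_effect(_cohort_frame(np.random.default_rng(5), effect=-15.0))
        assert res.F > 10 and res.p < 0.001

    def test_zero_response_degenerate(self):
        frame = _cohort_frame(np.random.default_rng(6))
        frame["erd_percent"] = 0.0
        res = glm_genotype_effect(frame)
        assert res.F == 0.0 and res.p == 1.0

    def test_collinear_design(self):
        frame = _cohort_frame(np.random.default_rng(7))
        frame["sex"] = np.where(frame["clu_group"] == "CC", "m", "f")
        with pytest.raises(ValueError, match="collinear"):
            glm_genotype_effect(frame)

    def test_missing_covariate(self):
        frame = _cohort_frame(np.random.default_rng(8))
        frame.loc[0, "age"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            glm_genotype_effect(frame)

    def test_single_group(self):
        frame = _cohort_frame(np.random.default_rng(9), n_cc=0)
        with pytest.raises(ValueError, match="genotype"):
            glm_genotype_effect(frame)


class TestDuncan:
    @pytest.mark.parametrize("diff", [0.5, 2.0, 4.0, 8.0])
    @pytest.mark.parametrize("n_a, n_b", [(10, 10), (8, 20)])
    @pytest.mark.parametrize("mse", [1.0, 9.0])
    def test_two_groups_equal_pooled_t(self, diff, n_a, n_b, mse):
        # with k=2 Duncan must reproduce the pooled two-sample t decision and p
        means = {"A": 0.0, "B": diff}
        sizes = {"A": n_a, "B": n_b}
        df_err = n_a + n_b - 2
        res = duncan_posthoc(means, mse, df_err, sizes)[0]
        t, _, p_t = summary_two_sample_test(
            SummaryGroup(n_a, 0.0, np.sqrt(mse / n_a)),
            SummaryGroup(n_b, diff, np.sqrt(mse / n_b)),
        )
        assert res.p == pytest.approx(p_t, rel=1e-6)
        assert res.significant == (p_t < 0.05)

    def test_identical_means(self):
        res = duncan_posthoc({"A": 1.0, "B": 1.0, "C": 1.0}, 2.0, 27, dict(A=10, B=10, C=10))
        assert not any(r.significant for r in res)
        assert all(r.p == pytest.approx(1.0, abs=1e-9) for r in res)

    def test_three_groups_step_down(self):
        # means 0, 0, 10 with tiny error: extreme pairs significant, near pair not
        res = duncan_posthoc({"A": 0.0, "B": 0.0, "C": 10.0}, 0.01, 27,
                             dict(A=10, B=10, C=10))
        by = {r.comparison: r for r in res}
        assert by["C vs A"].significant and by["C vs B"].significant
        assert not by["B vs A"].significant

    def test_critical_values_match_published_tables(self):
        # Duncan significant ranges at alpha=.05, df=20: 2.95 (k=2), 3.10 (k=3)
        assert sstats.studentized_range.ppf(0.95, 2, 20) == pytest.approx(2.95, abs=0.005)
        assert sstats.studentized_range.ppf(0.95**2, 3, 20) == pytest.approx(3.10, abs=0.005)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="variance"):
            duncan_posthoc({"A": 0.0, "B": 1.0}, 0.0, 10, dict(A=5, B=5))
        with pytest.raises(ValueError, match="2 groups"):
            duncan_posthoc({"A": 0.0}, 1.0, 10, dict(A=5))


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        res = pearson_age_correlation(x, x)
        assert res.r == pytest.approx(1.0) and res.p < 1e-10 and res.n == 10

    def test_independent_data_small_r(self):
        rng = np.random.default_rng(10)
        res = pearson_age_correlation(rng.normal(size=30), rng.normal(size=30))
        assert abs(res.r) < 0.5

    def test_p_matches_t_transform(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=25)
        y = 0.5 * x + rng.normal(size=25)
        res = pearson_age_correlation(x, y)
        t = res.r * np.sqrt((res.n - 2) / (1 - res.r**2))
        assert res.p == pytest.approx(2 * sstats.t.sf(abs(t), res.n - 2), rel=1e-9)

    def test_degenerate(self):
        with pytest.raises(DegenerateDataError):
            pearson_age_correlation(np.ones(10), np.arange(10.0))


class TestSummaryTests:
    def test_identical_groups(self):
        g = SummaryGroup(20, 5.0, 1.0)
        t, df, p = summary_two_sample_test(g, g)
        assert t == 0.0 and df == 38 and p == pytest.approx(1.0)

    def test_printed_verbal_fluency_row(self):
        # group summaries 34: 49.0 ± 2.4 vs 60: 46.4 ± 1.8 → p rounds to 0.39
        t, df, p = summary_two_sample_test(
            SummaryGroup(34, 49.0, 2.4), SummaryGroup(60, 46.4, 1.8)
        )
        assert df == 92
        assert p == pytest.approx(0.388, abs=0.005)

    def test_limit_behavior(self):
        t, _, p = summary_two_sample_test(
            SummaryGroup(50, 0.0, 1.0), SummaryGroup(50, 14.0, 1.0)
        )
        assert p < 1e-10

    def test_welch_variant(self):
        a, b = SummaryGroup(10, 0.0, 3.0), SummaryGroup(40, 1.0, 0.5)
        _, df_w, _ = summary_two_sample_test(a, b, equal_var=False)
        assert df_w < 48  # Welch df shrinks under variance heterogeneity

    def test_invalid_summary(self):
        with pytest.raises(ValueError):
            SummaryGroup(1, 0.0, 1.0)
        with pytest.raises(ValueError):
            SummaryGroup(10, 0.0, 0.0)


class TestProportion:
    def test_proportional_table(self):
        stat, p = proportion_test(np.array([[10, 20], [20, 40]]))
        assert stat == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_fisher_extreme_table(self):
        _, p = proportion_test(np.array([[10, 0], [0, 10]]), fisher=True)
        # direct hypergeometric enumeration: 2 / C(20,10)
        assert p == pytest.approx(2.0 / 184756, rel=1e-6)
        _, p_chi = proportion_test(np.array([[10, 0], [0, 10]]))
        assert p_chi < 0.001

    def test_empty_margin(self):
        with pytest.raises(ValueError, match="margin"):
            proportion_test(np.array([[0, 0], [5, 5]]))

    def test_non_integer(self):
        with pytest.raises(ValueError):
            proportion_test(np.array([[0.5, 1.0], [1.0, 1.0]]))
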