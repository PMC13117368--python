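"""Statistical-layer tests: t-tests, mixed ANOVA, correlations, power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dotprobe_eeg.group_stats import (PowerSpec, SummaryStats,
                                      bonferroni_adjust, mixed_anova_2x2,
                                      pearson_r, rm_anova_power,
                                      rm_anova_sample_size, t_independent,
                                      t_independent_from_summary)


class TestTTest:
    def test_equal_means_null(self):
        r = t_independent_from_summary(SummaryStats(1.0, 1.0, 10),
                                       SummaryStats(1.0, 2.0, 12))
        assert r.t == 0.0 and r.d == 0.0
        assert r.p == pytest.approx(1.0)

    def test_matches_scipy_pooled_and_welch(self, rng):
        x = rng.normal(1.0, 1.0, 14)
        y = rng.normal(0.2, 1.7, 9)
        for rule, equal_var in (("pooled", True), ("welch", False)):
            mine = t_independent(x, y, rule)
            ref = stats.ttest_ind(x, y, equal_var=equal_var)
            assert mine.t == pytest.approx(ref.statistic, abs=1e-12)
            assert mine.p == pytest.approx(ref.pvalue, abs=1e-12)
            lo, hi = ref.confidence_interval(0.95)
            assert mine.ci95 == pytest.approx((lo, hi), abs=1e-10)

    def test_raw_equals_summary_path(self, rng):
        x = rng.normal(0, 1, 20)
        y = rng.normal(0.4, 2, 15)
        raw = t_independent(x, y)
        summ = t_independent_from_summary(SummaryStats.of(x),
                                          SummaryStats.of(y))
        for attr in ("t", "df", "p", "d"):
            assert getattr(raw, attr) == pytest.approx(
                getattr(summ, attr), abs=1e-12)

    def test_cohens_d_pooled_definition(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(1, 1, 20)
        r = t_independent(x, y)
        sp = np.sqrt(((29 * x.var(ddof=1)) + 19 * y.var(ddof=1)) / 48)
        assert r.d == pytest.approx((x.mean() - y.mean()) / sp)

    def test_zero_variance_unequal_means_signals_infinite_t(self):
        r = t_independent_from_summary(SummaryStats(1.0, 0.0, 5),
                                       SummaryStats(0.0, 0.0, 5))
        assert np.isinf(r.t) and r.t > 0
        assert r.p == 0.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            t_independent(np.array([1.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            SummaryStats(0.0, -1.0, 5)


def design_matrix_anova_2x2(wide: pd.DataFrame) -> dict[str, float]:
    """Independent GLM oracle for the 2x2 mixed ANOVA (Type III F values).

    Between stratum: OLS of subject means on [1, group(sum-coded)];
    within stratum: OLS of the 2N stacked observations on subject dummies
    plus sum-coded condition and group x condition columns, with each
    effect's F from the extra sum of squares over the full within-model
    residual. Brute-force least squares throughout (no closed forms).
    """
    g = (wide["group"] == wide["group"].unique()[0]).to_numpy() * 2.0 - 1.0
    y1 = wide["congruent"].to_numpy()
    y2 = wide["incongruent"].to_numpy()
    n = len(wide)

    def ssr(X, y):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    # between stratum on subject means
    m = (y1 + y2) / 2.0
    X_full = np.column_stack([np.ones(n), g])
    sse = ssr(X_full, m)
    sse_red = ssr(np.ones((n, 1)), m)
    F_group = (sse_red - sse) / (sse / (n - 2))

    # within stratum on stacked data
    y = np.concatenate([y1, y2])
    cond = np.concatenate([-np.ones(n), np.ones(n)])     # sum-coded
    subj = np.vstack([np.eye(n), np.eye(n)])
    gx = np.concatenate([g, g]) * cond
    X = np.column_stack([subj, cond, gx])
    sse = ssr(X, y)
    df_err = 2 * n - (n + 2)
    F_cond = (ssr(np.column_stack([subj, gx]), y) - sse) / (sse / df_err)
    F_int = (ssr(np.column_stack([subj, cond]), y) - sse) / (sse / df_err)
    return {"group": F_group, "condition": F_cond, "interaction": F_int,
            "df_den": df_err}


class TestMixedAnova:
    @staticmethod
    def _random_wide(rng, n1=27, n2=18, g_eff=1.0, c_eff=0.3, i_eff=0.5):
        n = n1 + n2
        grp = np.array(["hsa"] * n1 + ["lsa"] * n2)
        base = rng.normal(0, 2, n)
        is_lsa = (grp == "lsa").astype(float)
        return pd.DataFrame({
            "subject": [f"s{i}" for i in range(n)],
            "group": grp,
            "congruent": base + rng.normal(0, 1, n) + g_eff * is_lsa,
            "incongruent": base + rng.normal(0, 1, n) + g_eff * is_lsa
            + c_eff + i_eff * is_lsa,
        })

    def test_df_one_and_n_minus_two(self, rng):
        res = mixed_anova_2x2(self._random_wide(rng))
        for eff in res.effects().values():
            assert eff.df == (1, 43)
        assert res.gg_epsilon == 1.0

    def test_null_group_construction(self):
        wide = pd.DataFrame({
            "subject": list("abcd"),
            "group": ["hsa", "hsa", "lsa", "lsa"],
            "congruent": [1.0, 2.0, 1.0, 2.0],
            "incongruent": [3.0, 4.0, 3.0, 4.0]})
        res = mixed_anova_2x2(wide)
        assert res.group.F == 0.0
        assert res.interaction.F == 0.0
        assert res.condition.F > 0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_design_matrix_oracle(self, seed):
        rng = np.random.default_rng(seed)
        wide = self._random_wide(rng)
        res = mixed_anova_2x2(wide)
        oracle = design_matrix_anova_2x2(wide)
        assert oracle["df_den"] == 43
        assert res.group.F == pytest.approx(oracle["group"], rel=1e-9)
        assert res.condition.F == pytest.approx(oracle["condition"], rel=1e-9)
        assert res.interaction.F == pytest.approx(oracle["interaction"],
                                                  rel=1e-9)

    def test_group_and_interaction_match_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        wide = self._random_wide(rng)
        long = wide.melt(id_vars=["subject", "group"],
                         value_vars=["congruent", "incongruent"],
                         var_name="condition", value_name="y")
        aov = pg.mixed_anova(data=long, dv="y", within="condition",
                             between="group", subject="subject"
                             ).set_index("Source")
        res = mixed_anova_2x2(wide)
        assert res.group.F == pytest.approx(aov.loc["group", "F"], rel=1e-6)
        assert res.group.partial_eta_sq == pytest.approx(
            aov.loc["group", "np2"], rel=1e-6)
        assert res.interaction.F == pytest.approx(
            aov.loc["Interaction", "F"], rel=1e-6)

    def test_partial_eta_sq_identity(self, rng):
        res = mixed_anova_2x2(self._random_wide(rng))
        for eff in res.effects().values():
            expected = eff.F * eff.df[0] / (eff.F * eff.df[0] + eff.df[1])
            assert eff.partial_eta_sq == pytest.approx(expected)

    def test_missing_cells_rejected(self):
        wide = pd.DataFrame({"subject": ["a", "b", "c", "d"],
                             "group": ["hsa", "hsa", "lsa", "lsa"],
                             "congruent": [1.0, 2.0, 3.0, 4.0],
                             "incongruent": [1.0, np.nan, 3.0, 4.0]})
        with pytest.raises(ValueError):
            mixed_anova_2x2(wide)


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson_r(x, x)[0] == pytest.approx(1.0)
        assert pearson_r(x, -2 * x + 3)[0] == pytest.approx(-1.0)

    def test_recovers_population_rho(self, rng):
        n, rho = 10_000, 0.5
        z = rng.standard_normal((2, n))
        x = z[0]
        y = rho * z[0] + np.sqrt(1 - rho ** 2) * z[1]
        r, p = pearson_r(x, y)
        assert abs(r - rho) < 0.03
        assert p < 1e-6

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson_r(np.ones(10), np.arange(10.0))
        with pytest.raises(ValueError):
            pearson_r(np.arange(2.0), np.arange(2.0))


class TestBonferroni:
    def test_cases(self):
        np.testing.assert_allclose(bonferroni_adjust([0.01]), [0.01])
        np.testing.assert_allclose(bonferroni_adjust([0.02, 0.03]),
                                   [0.04, 0.06])
        np.testing.assert_allclose(bonferroni_adjust([0.6, 0.9]), [1.0, 1.0])

    def test_order_preserving(self, rng):
        p = rng.uniform(0, 0.2, 10)
        adj = bonferroni_adjust(p)
        assert (np.argsort(adj) == np.argsort(p)).all()

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([1.2])


class TestPower:
    SPEC = PowerSpec(f=0.25, alpha=0.05, target_power=0.80,
                     n_groups=2, n_measurements=2, rho=0.5, epsilon=1.0)

    def test_monotone_in_n(self):
        powers = [rm_anova_power(self.SPEC, n) for n in range(6, 80, 4)]
        assert all(b >= a for a, b in zip(powers, powers[1:]))

    def test_larger_effect_needs_fewer_subjects(self):
        n_small = rm_anova_sample_size(self.SPEC)
        big = PowerSpec(f=0.5, alpha=0.05, target_power=0.80,
                        n_groups=2, n_measurements=2, rho=0.5, epsilon=1.0)
        assert rm_anova_sample_size(big) < n_small

    def test_unreachable_power_signalled(self):
        tiny = PowerSpec(f=0.01, alpha=0.05, target_power=0.99,
                         n_groups=2, n_measurements=2, rho=0.5, epsilon=1.0)
        with pytest.raises(ValueError):
            rm_anova_sample_size(tiny, n_cap=50)

    def test_analytic_power_matches_simulation(self):
        # Monte-Carlo oracle: simulate the mixed design at the returned N
        # under a pure condition effect of size f and count rejections of
        # the ANOVA condition test.
        spec = self.SPEC
        n_total = rm_anova_sample_size(spec)
        analytic = rm_anova_power(spec, n_total)
        rng = np.random.default_rng(123)
        n1 = n_total // 2
        n2 = n_total - n1
        delta = 2 * spec.f                      # condition mean difference
        n_rep, hits = 2000, 0
        f_crit = stats.f.ppf(0.95, 1, n_total - 2)
        for _ in range(n_rep):
            subj = rng.normal(0, np.sqrt(spec.rho), n_total)
            e1 = rng.normal(0, np.sqrt(1 - spec.rho), n_total)
            e2 = rng.normal(0, np.sqrt(1 - spec.rho), n_total)
            wide = pd.DataFrame({
                "subject": [f"s{i}" for i in range(n_total)],
                "group": ["a"] * n1 + ["b"] * n2,
                "congruent": subj + e1,
                "incongruent": subj + delta + e2})
            res = mixed_anova_2x2(wide)
            hits += res.condition.F > f_crit
        assert abs(hits / n_rep - analytic) < 0.03
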