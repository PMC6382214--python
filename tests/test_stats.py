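"""Association primitives against independent oracles: explicit least-squares
model comparisons for the type II ANCOVA, a projection-matrix oracle for the
population-adjusted correlation, pooled-t reduction for Welch, and null
calibration of the regression F-test."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import mireqtl as m
from mireqtl.stats import DegenerateInputError

from conftest import random_small_dataset


def _ols_rss(X, y):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def ancova_oracle(y, g, pop, with_interaction=False):
    """Type II genotype/population F-tests by explicit two-fit model
    comparison (independent of the package implementation)."""
    y = np.asarray(y, float)
    g = np.asarray(g, float)
    levels = np.unique(pop)
    D = np.column_stack([(pop == lv).astype(float) for lv in levels[1:]])
    one = np.ones((len(y), 1))
    X_main = np.column_stack([one, g[:, None], D])
    X_nog = np.column_stack([one, D])
    X_nopop = np.column_stack([one, g[:, None]])
    if with_interaction:
        inter = g[:, None] * D
        X_big = np.column_stack([X_main, inter])
    else:
        X_big = X_main
    rss_big = _ols_rss(X_big, y)
    df_resid = len(y) - X_big.shape[1]
    mse = rss_big / df_resid
    out = {}
    for name, X_red, df_num in (("g", X_nog, 1),
                                ("pop", X_nopop, len(levels) - 1)):
        ss = _ols_rss(X_red, y) - _ols_rss(X_main, y)
        F = (ss / df_num) / mse
        out[name] = (F, scipy.stats.f.sf(F, df_num, df_resid))
    if with_interaction:
        ss = _ols_rss(X_main, y) - rss_big
        df_num = X_big.shape[1] - X_main.shape[1]
        F = (ss / df_num) / mse
        out["inter"] = (F, scipy.stats.f.sf(F, df_num, df_resid))
    return out


def partial_oracle(x, y, pop):
    """Population-adjusted correlation via an explicit projection matrix."""
    levels = np.unique(pop)
    D = np.column_stack([(pop == lv).astype(float) for lv in levels])
    P = np.eye(len(x)) - D @ np.linalg.pinv(D.T @ D) @ D.T
    rx, ry = P @ x, P @ y
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


class TestSlr:
    def test_perfect_fit(self):
        g = np.tile([0.0, 1.0, 2.0], 3)
        res = m.slr_ftest(2.0 * g, g)
        assert res.estimate == pytest.approx(2.0)
        assert res.p_value == 0.0

    def test_constant_genotype_rejected(self):
        with pytest.raises(DegenerateInputError):
            m.slr_ftest([1.0, 2.0, 3.0], [1, 1, 1])

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(1000):
            g = rng.integers(0, 3, 50).astype(float)
            if np.ptp(g) == 0:
                continue
            ps.append(m.slr_ftest(rng.standard_normal(50), g).p_value)
        assert scipy.stats.kstest(ps, "uniform").pvalue > 0.01

    def test_matches_scipy_linregress(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, 40).astype(float)
        y = rng.standard_normal(40) + 0.5 * g
        res = m.slr_ftest(y, g)
        lr = scipy.stats.linregress(g, y)
        assert res.estimate == pytest.approx(lr.slope, abs=1e-12)
        assert res.p_value == pytest.approx(lr.pvalue, abs=1e-12)
        assert res.statistic == pytest.approx(lr.rvalue**2 /
                                              (1 - lr.rvalue**2) * 38, rel=1e-10)


class TestAnova:
    def test_single_group_rejected(self):
        with pytest.raises(DegenerateInputError):
            m.anova_oneway([1.0, 2.0, 3.0], ["A", "A", "A"])

    def test_separated_groups(self):
        res = m.anova_oneway([1, 1, 1, 5, 5, 5], ["A"] * 3 + ["B"] * 3)
        assert res.p_value == 0.0

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal(60)
        grp = rng.choice(list("ABC"), 60)
        res = m.anova_oneway(y, grp)
        ref = scipy.stats.f_oneway(*(y[grp == l] for l in "ABC"))
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(3)
        rejections = 0
        for _ in range(1000):
            y = rng.standard_normal(30)
            grp = np.repeat(list("ABC"), 10)
            rejections += m.anova_oneway(y, grp).p_value < 0.05
        assert abs(rejections / 1000 - 0.05) < 0.02


class TestAncovaType2:
    @pytest.mark.parametrize("with_interaction", [False, True])
    def test_matches_explicit_model_comparison_oracle(self, with_interaction):
        rng = np.random.default_rng(4)
        for _ in range(100):
            df = random_small_dataset(rng)
            try:
                res = m.ancova_type2(df["y"], df["g"], df["pop"],
                                     with_interaction=with_interaction)
            except DegenerateInputError:
                continue
            oracle = ancova_oracle(df["y"].to_numpy(), df["g"].to_numpy(),
                                   df["pop"].to_numpy(), with_interaction)
            assert res.genotype.statistic == pytest.approx(oracle["g"][0], abs=1e-8)
            assert res.genotype.p_value == pytest.approx(oracle["g"][1], abs=1e-8)
            assert res.population.statistic == pytest.approx(oracle["pop"][0], abs=1e-8)
            if with_interaction:
                assert res.interaction.statistic == pytest.approx(
                    oracle["inter"][0], abs=1e-8)

    def test_balanced_orthogonal_design_type2_equals_type1(self):
        # balanced design with genotype orthogonal to population
        g = np.tile([0.0, 1.0, 2.0], 20)
        pop = np.repeat(["A", "B"], 30)
        rng = np.random.default_rng(5)
        y = 0.5 * g + (pop == "B") * 2 + rng.standard_normal(60)
        res = m.ancova_type2(y, g, pop)
        # type I: sequential SS with genotype first equals type II here
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm
        fit = smf.ols("y ~ g + C(pop)", data=pd.DataFrame(
            {"y": y, "g": g, "pop": pop})).fit()
        t1 = anova_lm(fit, typ=1)
        assert res.genotype.statistic == pytest.approx(t1.loc["g", "F"], rel=1e-10)

    def test_confounded_design_rejected(self):
        # genotype constant within every population level -> singular
        g = np.repeat([0.0, 2.0], 10)
        pop = np.repeat(["A", "B"], 10)
        y = np.random.default_rng(6).standard_normal(20)
        with pytest.raises(DegenerateInputError):
            m.ancova_type2(y, g, pop)

    def test_genotype_slope_equals_within_population_centered_slr(self):
        rng = np.random.default_rng(7)
        df = random_small_dataset(rng)
        res = m.ancova_type2(df["y"], df["g"], df["pop"])
        yc = df.groupby("pop")["y"].transform(lambda s: s - s.mean())
        gc = df.groupby("pop")["g"].transform(lambda s: s - s.mean())
        slope = float(np.dot(gc, yc) / np.dot(gc, gc))
        assert res.genotype.estimate == pytest.approx(slope, abs=1e-10)


class TestWelch:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = m.welch_t(a, a.copy())
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_large_shift(self):
        res = m.welch_t(np.array([1.0, 2.0, 3.0]), np.array([11.0, 12.0, 13.0]))
        assert res.p_value < 0.01
        assert res.estimate == pytest.approx(-10.0)

    def test_reduces_to_pooled_t_under_equal_variance_equal_n(self):
        rng = np.random.default_rng(8)
        a = rng.standard_normal(15)
        b = rng.standard_normal(15) + 0.4
        # force exactly equal sample variances by standardizing both
        a = (a - a.mean()) / a.std(ddof=1)
        b = (b - b.mean()) / b.std(ddof=1) + 0.4
        welch = m.welch_t(a, b)
        pooled = scipy.stats.ttest_ind(a, b, equal_var=True)
        assert welch.statistic == pytest.approx(pooled.statistic, abs=1e-10)
        assert welch.p_value == pytest.approx(pooled.pvalue, abs=1e-10)
        assert welch.df == pytest.approx(28.0, abs=1e-8)

    def test_tiny_group_rejected(self):
        with pytest.raises(DegenerateInputError):
            m.welch_t([1.0], [1.0, 2.0])


class TestLmm:
    def test_recovers_slope_on_simulated_cohort(self):
        design = m.CohortDesign()
        hits, n_seeds = 0, 40
        for s in range(n_seeds):
            data = m.simulate_cohort(design, seed=s)
            res = m.lmm_random_intercept(data["host"]["host"],
                                         data["genotypes"]["snp1"],
                                         data["metadata"]["population"])
            assert res.converged
            se = abs(res.fixed_slope) / np.sqrt(res.genotype_wald.statistic)
            hits += abs(res.fixed_slope - design.slope_host) <= 1.96 * se
        assert hits / n_seeds >= 0.85

    def test_zero_population_effect_boundary_variance(self):
        rng = np.random.default_rng(9)
        g = rng.integers(0, 3, 200).astype(float)
        y = 0.5 * g + rng.standard_normal(200)
        pop = rng.choice(["A", "B", "C"], 200)
        res = m.lmm_random_intercept(y, g, pop)
        assert res.random_intercept_sd == pytest.approx(0.0, abs=0.1)

    def test_agrees_with_ancova_direction_on_strong_effects(self):
        agree, n_seeds = 0, 30
        for s in range(n_seeds):
            data = m.simulate_cohort(m.planted_scan_design(), seed=s)
            y = data["host"]["host"]
            g = data["genotypes"]["snp1"]
            pop = data["metadata"]["population"]
            a = m.ancova_type2(y, g, pop).genotype.p_value < 0.05
            l = m.lmm_random_intercept(y, g, pop)
            agree += l.converged and (l.genotype_wald.p_value < 0.05) == a
        assert agree / n_seeds >= 0.95


class TestCorrelations:
    def test_pearson_identity(self):
        x = np.arange(10.0)
        res = m.pearson(x, x)
        assert res.estimate == pytest.approx(1.0)

    def test_pearson_matches_target_on_exact_dataset(self, nontransitivity_exact):
        t = nontransitivity_exact
        assert m.pearson(t["genotype"], t["rna1"]).estimate == pytest.approx(0.472, abs=1e-8)

    def test_partial_equals_plain_with_single_population(self):
        rng = np.random.default_rng(10)
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        plain = m.pearson(x, y)
        adj = m.partial_pearson(x, y, np.repeat("A", 30))
        assert adj.estimate == pytest.approx(plain.estimate, abs=1e-12)

    def test_partial_removes_population_confounding(self):
        rng = np.random.default_rng(11)
        pop = np.repeat(["A", "B"], 50)
        x = rng.standard_normal(100) + (pop == "A") * 100
        y = rng.standard_normal(100) + (pop == "A") * 100
        assert m.pearson(x, y).estimate > 0.9
        assert abs(m.partial_pearson(x, y, pop).estimate) < 0.3

    @pytest.mark.filterwarnings("ignore:population level")
    def test_partial_matches_projection_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            n = int(rng.integers(10, 40))
            pop = rng.choice(list("ABC"), n)
            if len(np.unique(pop)) < 2:
                continue
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            res = m.partial_pearson(x, y, pop)
            assert res.estimate == pytest.approx(partial_oracle(x, y, pop), abs=1e-10)

    def test_singleton_population_warns(self):
        rng = np.random.default_rng(13)
        pop = np.array(["A"] * 10 + ["B"])
        with pytest.warns(UserWarning):
            m.partial_pearson(rng.standard_normal(11), rng.standard_normal(11), pop)


class TestInvariances:
    def test_sample_permutation_changes_nothing(self, simpson_exact):
        t = simpson_exact
        perm = np.random.default_rng(14).permutation(len(t))
        tp = t.iloc[perm]
        for fn, args in [
            (m.slr_ftest, ("expression", "genotype")),
            (m.anova_oneway, ("expression", "population")),
        ]:
            a = fn(t[args[0]], t[args[1]])
            b = fn(tp[args[0]].to_numpy(), tp[args[1]].to_numpy())
            assert a.statistic == pytest.approx(b.statistic, abs=1e-10)
        a = m.ancova_type2(t["expression"], t["genotype"], t["population"])
        b = m.ancova_type2(tp["expression"].to_numpy(), tp["genotype"].to_numpy(),
                           tp["population"].to_numpy())
        assert a.genotype.statistic == pytest.approx(b.genotype.statistic, abs=1e-8)
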