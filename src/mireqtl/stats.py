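"""Association-test primitives for population-structured eQTL analysis.

Every test operates on plain numeric arrays and returns a :class:`TestResult`
(or a composite result) carrying the statistic, its degrees of freedom, the
two-sided p-value and, where meaningful, an effect estimate.  Genotypes are
always coded additively as alternate-allele counts (0/1/2).  Missing values
are handled by the callers via pairwise-complete deletion; the primitives
here require complete input.

The panel covers the classical toolkit for cis-eQTL mapping in multi-
population cohorts:

* simple linear regression F-test (``slr_ftest``) — the pooled, population-
  blind association;
* one-way ANOVA on the population label (``anova_oneway``);
* ANCOVA with type II sums of squares (``ancova_type2``) — genotype tested
  while adjusting for the population main effect, optionally with a
  genotype-by-population interaction;
* Welch's two-sample t-test (``welch_t``) for pairwise genotype-group
  comparisons;
* a random-intercept linear mixed model fitted by REML with a type II Wald
  chi-square genotype test (``lmm_random_intercept``);
* Pearson and population-adjusted (partial) Pearson correlation.

The contrast between ``slr_ftest`` and ``ancova_type2`` on the same data is
what exposes Simpson-like masking of an eQTL by population stratification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "TestResult",
    "AncovaResult",
    "LmmResult",
    "DegenerateInputError",
    "slr_ftest",
    "anova_oneway",
    "ancova_type2",
    "welch_t",
    "lmm_random_intercept",
    "pearson",
    "partial_pearson",
]


class DegenerateInputError(ValueError):
    """Raised when a test's input admits no informative answer
    (constant genotype, a single group, zero variance, rank deficiency)."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test.

    Attributes
    ----------
    statistic : float
        Test statistic (F, t, chi-square or r depending on the test).
    df : float | tuple[float, float]
        Degrees of freedom; a pair for F-tests.
    p_value : float
        Two-sided p-value in [0, 1].
    estimate : float | None
        Effect estimate on the natural scale of the test: regression slope,
        mean difference (a − b) or correlation coefficient.
    n : int
        Number of observations used.
    """

    __test__ = False  # not a pytest class despite the name

    statistic: float
    df: float | tuple[float, float]
    p_value: float
    estimate: float | None = None
    n: int = 0

    def __post_init__(self) -> None:
        if not np.isnan(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class AncovaResult:
    """Type II ANCOVA panel for expression ~ genotype + population.

    ``interaction`` is present only when the genotype-by-population term was
    requested; the main-effect tests then still compare main-effects models
    (marginality), but use the residual mean square of the largest model.
    """

    genotype: TestResult
    population: TestResult
    interaction: TestResult | None
    residual_df: int
    n: int = 0


@dataclass(frozen=True)
class LmmResult:
    """Random-intercept mixed model: expression ~ genotype + (1 | population).

    ``genotype_wald`` is the type II Wald chi-square test (1 df) on the fixed
    genotype slope; variance components are REML estimates.
    """

    genotype_wald: TestResult | None
    fixed_slope: float
    random_intercept_sd: float
    residual_sd: float
    converged: bool
    n: int = 0


def _clean_xy(*arrays: np.ndarray) -> tuple[np.ndarray, ...]:
    out = tuple(np.asarray(a, dtype=float) for a in arrays)
    n = {a.shape[0] for a in out}
    if len(n) != 1:
        raise ValueError("input vectors have unequal lengths")
    return out


def slr_ftest(y, g) -> TestResult:
    """F-test of the simple linear regression of expression on allele count.

    Equivalent to a linear model with the (numeric 0/1/2) genotype as the only
    predictor: F = (regression SS / 1) / (residual SS / (n − 2)), referred to
    F(1, n − 2).  The estimate is the per-allele slope.
    """
    y, g = _clean_xy(y, g)
    n = y.shape[0]
    if n < 3:
        raise DegenerateInputError("SLR needs at least 3 samples")
    if np.ptp(g) == 0:
        raise DegenerateInputError("genotype is constant; no slope to test")
    gc = g - g.mean()
    yc = y - y.mean()
    sxx = gc @ gc
    slope = (gc @ yc) / sxx
    ss_total = yc @ yc
    ss_reg = slope * slope * sxx
    ss_res = max(ss_total - ss_reg, 0.0)
    df_res = n - 2
    if ss_res == 0.0:
        if ss_reg == 0.0:
            raise DegenerateInputError("expression is constant")
        return TestResult(np.inf, (1.0, float(df_res)), 0.0, float(slope), n)
    f = (ss_reg / 1.0) / (ss_res / df_res)
    p = float(scipy.stats.f.sf(f, 1, df_res))
    return TestResult(float(f), (1.0, float(df_res)), p, float(slope), n)


def anova_oneway(y, group) -> TestResult:
    """One-way ANOVA of expression across population (or other) groups."""
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    levels = pd.unique(group)
    k = len(levels)
    if k < 2:
        raise DegenerateInputError("one-way ANOVA needs at least 2 groups")
    n = y.shape[0]
    if n - k < 1:
        raise DegenerateInputError("no residual degrees of freedom")
    samples = [y[group == lv] for lv in levels]
    grand = y.mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df1, df2 = k - 1, n - k
    if ss_within == 0.0:
        p = 0.0 if ss_between > 0 else 1.0
        return TestResult(np.inf if ss_between > 0 else 0.0,
                          (float(df1), float(df2)), p, None, n)
    f = (ss_between / df1) / (ss_within / df2)
    return TestResult(float(f), (float(df1), float(df2)),
                      float(scipy.stats.f.sf(f, df1, df2)), None, n)


def _ancova_frame(y, g, pop) -> pd.DataFrame:
    y, g = _clean_xy(y, g)
    return pd.DataFrame({"y": y, "g": g, "pop": pd.Categorical(np.asarray(pop))})


def ancova_type2(y, g, pop, with_interaction: bool = False) -> AncovaResult:
    """ANCOVA of expression on numeric genotype and categorical population.

    Type II sums of squares: each main effect is tested by comparing the
    full main-effects model against the model dropping that term, respecting
    marginality (main-effect comparisons exclude the interaction); the
    interaction, when requested, is tested against the main-effects model.
    All F-tests use the residual mean square of the largest fitted model.

    Returns an :class:`AncovaResult`; the genotype estimate is the adjusted
    per-allele slope from the main-effects model.
    """
    df = _ancova_frame(y, g, pop)
    n = len(df)
    if df["pop"].nunique() < 2:
        raise DegenerateInputError("population factor needs at least 2 levels")
    if df["g"].nunique() < 2:
        raise DegenerateInputError("genotype is constant")
    formula = "y ~ g + C(pop)" + (" + g:C(pop)" if with_interaction else "")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.ols(formula, data=df).fit()
    if fit.df_resid < 1 or np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise DegenerateInputError("singular design: genotype confounded with population")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tab = anova_lm(fit, typ=2)
    main_fit = fit if not with_interaction else smf.ols("y ~ g + C(pop)", data=df).fit()
    slope = float(main_fit.params["g"])

    def row(name: str, estimate: float | None = None) -> TestResult:
        r = tab.loc[name]
        return TestResult(float(r["F"]), (float(r["df"]), float(fit.df_resid)),
                          float(r["PR(>F)"]), estimate, n)

    interaction = row("g:C(pop)") if with_interaction else None
    return AncovaResult(genotype=row("g", slope), population=row("C(pop)"),
                        interaction=interaction, residual_df=int(fit.df_resid), n=n)


def welch_t(a, b) -> TestResult:
    """Two-sample two-tailed Welch t-test with Satterthwaite df.

    The estimate is mean(a) − mean(b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DegenerateInputError("Welch t-test needs >= 2 samples per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise DegenerateInputError("both groups have zero variance")
    res = scipy.stats.ttest_ind(a, b, equal_var=False)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue),
                      float(a.mean() - b.mean()), len(a) + len(b))


def lmm_random_intercept(y, g, pop) -> LmmResult:
    """Random-intercept LMM: expression ~ genotype with population as a
    random-effects term, fitted by restricted maximum likelihood.

    The genotype effect is assessed by a type II Wald chi-square test with
    1 df: chi2 = (slope / SE)^2.  Non-convergence yields ``converged=False``
    with the Wald test absent.
    """
    y, g = _clean_xy(y, g)
    pop = np.asarray(pop)
    n = y.shape[0]
    if len(pd.unique(pop)) < 2:
        raise DegenerateInputError("LMM needs at least 2 populations")
    if n < 4:
        raise DegenerateInputError("LMM needs at least 4 samples")
    exog = sm.add_constant(g)
    model = sm.MixedLM(y, exog, groups=pop)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(reml=True, method=["lbfgs", "powell"])
        converged = bool(getattr(fit, "converged", True))
    except Exception:
        return LmmResult(None, np.nan, np.nan, np.nan, False, n)
    slope = float(fit.fe_params[1])
    se = float(fit.bse_fe[1])
    re_sd = float(np.sqrt(max(np.asarray(fit.cov_re)[0, 0], 0.0)))
    resid_sd = float(np.sqrt(fit.scale))
    if not converged or not np.isfinite(se) or se == 0.0:
        return LmmResult(None, slope, re_sd, resid_sd, False, n)
    chi2 = (slope / se) ** 2
    wald = TestResult(float(chi2), 1.0, float(scipy.stats.chi2.sf(chi2, 1)),
                      slope, n)
    return LmmResult(wald, slope, re_sd, resid_sd, True, n)


def pearson(x, y) -> TestResult:
    """Pearson product-moment correlation with its two-tailed p-value."""
    x, y = _clean_xy(x, y)
    n = x.shape[0]
    if n < 3:
        raise DegenerateInputError("Pearson correlation needs >= 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant input to Pearson correlation")
    r, p = scipy.stats.pearsonr(x, y)
    return TestResult(float(r), float(n - 2), float(p), float(r), n)


def partial_pearson(x, y, pop) -> TestResult:
    """Population-adjusted Pearson correlation.

    Both variables are residualized on population indicator columns (with
    intercept) by least squares; the correlation of the residuals is referred
    to a t-distribution with n − 2 − (levels − 1) degrees of freedom, the
    standard partial-correlation convention for a categorical adjustment.
    """
    x, y = _clean_xy(x, y)
    pop = np.asarray(pop)
    levels = pd.unique(pop)
    k = len(levels)
    n = x.shape[0]
    if n < k + 2:
        raise DegenerateInputError("too few samples for population adjustment")
    singletons = [lv for lv in levels if (pop == lv).sum() == 1]
    if singletons:
        warnings.warn(
            f"population level(s) with a single sample contribute zero residuals: {singletons}",
            stacklevel=2,
        )
    # design of population indicators spans the intercept
    design = (pop[:, None] == levels[None, :]).astype(float)
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise DegenerateInputError("all-constant residuals after population adjustment")
    r = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    df = n - 2 - (k - 1)
    r_clipped = min(max(r, -1.0), 1.0)
    if abs(r_clipped) == 1.0:
        p = 0.0
    else:
        t = r_clipped * np.sqrt(df / (1.0 - r_clipped**2))
        p = float(2.0 * scipy.stats.t.sf(abs(t), df))
    return TestResult(r_clipped, float(df), p, r_clipped, n)
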