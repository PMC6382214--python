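"""Per-feature eQTL analysis: the full association panel for one
(variant, transcript) pair in a population-structured cohort.

The central objects follow the model/results idiom: build an
:class:`EqtlModel` from an expression vector, an additive genotype vector
and a population label, call :meth:`EqtlModel.fit`, and read everything off
the returned :class:`EqtlResults` — pooled simple linear regression,
one-way population ANOVA, type II ANCOVA (optionally with interaction), an
optional random-intercept mixed model, pairwise Welch t-tests between
genotype groups, and plain plus population-adjusted correlations.

The panel is designed so that population-confounded associations are
visible at a glance: a non-significant SLR next to a significant ANCOVA
genotype effect is the signature of Simpson-like masking (see
:mod:`mireqtl.paradox`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import stats as st
from .stats import (AncovaResult, DegenerateInputError, LmmResult, TestResult)

__all__ = ["ExpressionTable", "EqtlModel", "EqtlResults", "EqtlRecord",
           "average_replicates", "run_eqtl", "ratio_eqtl"]


@dataclass
class ExpressionTable:
    """samples × features numeric table with a scale tag and feature kind.

    ``scale`` is ``"log2"`` (microarray intensities) or ``"linear"`` (RPKM,
    normalized counts, scaled 2^-dCt values); analyses run on the stored
    scale.  ``kind`` is ``"mRNA"`` or ``"miRNA"``.
    """

    values: pd.DataFrame
    scale: str = "linear"
    kind: str = "mRNA"

    def __post_init__(self) -> None:
        if self.scale not in ("log2", "linear"):
            raise ValueError(f"unknown scale tag: {self.scale}")
        if self.kind not in ("mRNA", "miRNA"):
            raise ValueError(f"unknown feature kind: {self.kind}")


def average_replicates(expr: ExpressionTable,
                       replicate_map: Mapping[str, str]) -> ExpressionTable:
    """Average technical replicates into one row per individual.

    ``replicate_map`` maps each replicate (row) id to its individual id.
    Values are averaged arithmetically on the table's stored scale; missing
    values are dropped pairwise (the mean of the present replicates is
    used).  Rows not present in the map are kept under their own id.
    """
    ids = [replicate_map.get(r, r) for r in expr.values.index]
    averaged = expr.values.groupby(pd.Index(ids, name=expr.values.index.name)).mean()
    return ExpressionTable(averaged, scale=expr.scale, kind=expr.kind)


@dataclass(frozen=True)
class EqtlRecord:
    """All statistics for one (variant, feature) pair."""

    feature_id: str
    variant_id: str
    n: int
    genotype_counts: dict[int, int]
    genotype_means: dict[int, float]
    slr: TestResult
    anova_population: TestResult
    ancova: AncovaResult
    lmm: LmmResult | None
    pairwise_welch: dict[tuple[int, int], TestResult]
    r_plain: TestResult
    r_adjusted: TestResult
    alpha: float = 0.05
    scale: str = "linear"

    @property
    def significant(self) -> bool:
        """True iff the ANCOVA genotype effect clears alpha."""
        return self.ancova.genotype.p_value < self.alpha


class EqtlResults:
    """Fitted eQTL panel; thin results wrapper around an :class:`EqtlRecord`."""

    def __init__(self, record: EqtlRecord):
        self.record = record

    def __getattr__(self, name):
        return getattr(self.record, name)

    def summary(self) -> str:
        r = self.record
        lines = [
            f"eQTL panel: {r.feature_id} ~ {r.variant_id}  (n = {r.n}, scale = {r.scale})",
            "-" * 64,
            f"{'genotype group':<20}{'n':>6}{'mean':>12}",
        ]
        for g in sorted(r.genotype_counts):
            lines.append(f"{g:<20}{r.genotype_counts[g]:>6}{r.genotype_means[g]:>12.4g}")
        lines.append("-" * 64)
        lines.append(f"{'SLR (genotype only)':<28}F = {r.slr.statistic:<10.4g}p = {r.slr.p_value:.4g}")
        lines.append(f"{'ANOVA (population only)':<28}F = {r.anova_population.statistic:<10.4g}"
                     f"p = {r.anova_population.p_value:.4g}")
        lines.append(f"{'ANCOVA genotype':<28}F = {r.ancova.genotype.statistic:<10.4g}"
                     f"p = {r.ancova.genotype.p_value:.4g}")
        lines.append(f"{'ANCOVA population':<28}F = {r.ancova.population.statistic:<10.4g}"
                     f"p = {r.ancova.population.p_value:.4g}")
        if r.ancova.interaction is not None:
            lines.append(f"{'ANCOVA interaction':<28}F = {r.ancova.interaction.statistic:<10.4g}"
                         f"p = {r.ancova.interaction.p_value:.4g}")
        if r.lmm is not None and r.lmm.genotype_wald is not None:
            lines.append(f"{'LMM Wald chi2 (1 df)':<28}X2 = {r.lmm.genotype_wald.statistic:<9.4g}"
                         f"p = {r.lmm.genotype_wald.p_value:.4g}")
        for (a, b), t in r.pairwise_welch.items():
            lines.append(f"{f'Welch {a} vs {b}':<28}t = {t.statistic:<10.4g}p = {t.p_value:.4g}")
        lines.append(f"{'Pearson r (plain)':<28}r = {r.r_plain.estimate:<10.4g}p = {r.r_plain.p_value:.4g}")
        lines.append(f"{'Pearson r (pop-adjusted)':<28}r = {r.r_adjusted.estimate:<10.4g}"
                     f"p = {r.r_adjusted.p_value:.4g}")
        return "\n".join(lines)


class EqtlModel:
    """eQTL association model for one feature and one additive variant.

    Parameters
    ----------
    y : array-like
        Expression values on the analysis scale.
    genotype : array-like
        Alternate/risk-allele counts 0/1/2 (NaN allowed; dropped pairwise).
    population : array-like
        Population label per sample.
    feature_id, variant_id : str
        Identifiers carried into the results.
    scale : str
        Scale tag recorded in the results (``"log2"`` or ``"linear"``).
    """

    def __init__(self, y, genotype, population, *, feature_id: str = "feature",
                 variant_id: str = "variant", scale: str = "linear"):
        y = np.asarray(y, dtype=float)
        g = np.asarray(genotype, dtype=float)
        pop = np.asarray(population, dtype=object)
        if not (len(y) == len(g) == len(pop)):
            raise ValueError("y, genotype and population must have equal length")
        keep = ~(np.isnan(y) | np.isnan(g))
        self.y = y[keep]
        self.g = g[keep]
        self.pop = pop[keep]
        self.feature_id = feature_id
        self.variant_id = variant_id
        self.scale = scale

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, *, y: str, genotype: str,
                       population: str, **kwargs) -> "EqtlModel":
        return cls(data[y], data[genotype], data[population], **kwargs)

    def fit(self, *, interaction: bool = False, lmm: bool = False,
            alpha: float = 0.05) -> EqtlResults:
        y, g, pop = self.y, self.g, self.pop
        if len(y) < 3:
            raise DegenerateInputError(
                f"{self.variant_id}: fewer than 3 complete samples")
        groups = np.unique(g)
        if len(groups) < 2:
            raise DegenerateInputError(
                f"{self.variant_id}: a single genotype group present")
        counts = {int(v): int((g == v).sum()) for v in groups}
        means = {int(v): float(y[g == v].mean()) for v in groups}

        slr = st.slr_ftest(y, g)
        anova_pop = st.anova_oneway(y, pop)
        ancova = st.ancova_type2(y, g, pop, with_interaction=interaction)
        lmm_res = st.lmm_random_intercept(y, g, pop) if lmm else None

        welch: dict[tuple[int, int], TestResult] = {}
        eligible = [int(v) for v in groups if counts[int(v)] >= 2]
        for i, a in enumerate(eligible):
            for b in eligible[i + 1:]:
                ya, yb = y[g == a], y[g == b]
                if np.ptp(ya) == 0 and np.ptp(yb) == 0:
                    continue
                welch[(a, b)] = st.welch_t(ya, yb)

        r_plain = st.pearson(g, y)
        r_adj = st.partial_pearson(g, y, pop)

        record = EqtlRecord(
            feature_id=self.feature_id, variant_id=self.variant_id,
            n=len(y), genotype_counts=counts, genotype_means=means,
            slr=slr, anova_population=anova_pop, ancova=ancova, lmm=lmm_res,
            pairwise_welch=welch, r_plain=r_plain, r_adjusted=r_adj,
            alpha=alpha, scale=self.scale,
        )
        return EqtlResults(record)


def run_eqtl(y, genotype, population, *, feature_id: str = "feature",
             variant_id: str = "variant", scale: str = "linear",
             interaction: bool = False, lmm: bool = False,
             alpha: float = 0.05) -> EqtlResults:
    """Functional wrapper: build an :class:`EqtlModel` and fit it."""
    model = EqtlModel(y, genotype, population, feature_id=feature_id,
                      variant_id=variant_id, scale=scale)
    return model.fit(interaction=interaction, lmm=lmm, alpha=alpha)


def ratio_eqtl(mir, host, genotype, population, *, feature_id: str = "mir/host",
               variant_id: str = "variant", **fit_kwargs) -> EqtlResults:
    """eQTL of the per-sample miRNA / host-transcript ratio.

    Both inputs must be on the linear scale and the host values strictly
    positive; the ratio cancels variation shared by the two transcripts
    (their common primary-transcript / scaling component), which can make
    the genotype effect on processing visible when neither single-feature
    association is significant.
    """
    mir = np.asarray(mir, dtype=float)
    host = np.asarray(host, dtype=float)
    bad = np.where(~np.isnan(host) & (host <= 0))[0]
    if bad.size:
        raise ValueError(
            f"host expression must be strictly positive for the ratio; "
            f"offending sample indices: {bad.tolist()[:10]}")
    return run_eqtl(mir / host, genotype, population, feature_id=feature_id,
                    variant_id=variant_id, scale="linear", **fit_kwargs)
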