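"""Synthetic data generators for eQTL paradox studies.

Three generators are provided:

``SimpsonDesign`` / ``make_simpson_dataset``
    A two-population cohort in which the genotype–expression association is
    strong and parallel within each population but vanishes when the
    populations are pooled, because the risk allele is the major allele in
    one population and the minor allele in the other.  In *exact* mode the
    empirical cell means equal the nominal means and the pooled per-genotype
    means equal the pooled target exactly, so the pooled regression slope is
    identically zero — the textbook Simpson-like masking.

``NonTransitivityDesign`` / ``make_nontransitivity_dataset``
    A three-variable dataset (allele count, two RNA levels) whose sample
    Pearson correlation matrix can be forced, in exact mode, to equal an
    arbitrary positive-definite target — demonstrating that r(g, RNA1) > 0
    and r(RNA1, RNA2) > 0 are compatible with r(g, RNA2) < 0.

``CohortDesign`` / ``simulate_cohort``
    A multi-population cohort in the style of lymphoblastoid-cell-line
    RNA-seq panels: Hardy–Weinberg genotypes with population-specific allele
    frequencies, a host-gene transcript and a mature miRNA processed from
    the same primary transcript (shared multiplicative expression factor),
    additive genotype effects of configurable (typically opposite) sign on
    the two molecules, and zero-inflated miRNA measurements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimpsonDesign",
    "NonTransitivityDesign",
    "PopulationSpec",
    "CohortDesign",
    "DesignInfeasibleError",
    "solve_simpson_design",
    "make_simpson_dataset",
    "make_nontransitivity_dataset",
    "simulate_cohort",
    "null_cohort_design",
    "planted_scan_design",
    "pcr_cohort_design",
    "write_dataset",
]

_MEAN_TOL = 1e-9


class DesignInfeasibleError(ValueError):
    """The requested design admits no valid dataset (e.g. a pooled mean
    outside the convex hull of the population means, or a non-positive-
    definite correlation target)."""


# ---------------------------------------------------------------------------
# Simpson-like masking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimpsonDesign:
    """Two-population design that masks a strong eQTL on pooling.

    Parameters
    ----------
    n_per_genotype : int
        Total individuals in each pooled genotype group (default 60, i.e.
        180 individuals overall).
    pop_means : tuple of two length-3 sequences
        Per-genotype expression means for the two populations; defaults
        (15, 10, 5) and (30, 25, 20) — a per-allele slope of −5 within each
        population.
    pooled_mean : float
        Target pooled mean for every genotype group (default 18).
    residual_sd : float
        Within-cell noise standard deviation (default 2.0).
    exact : bool
        If True (default), residuals are centered and rescaled within each
        population × genotype cell so empirical cell means and the pooled
        means are exact.
    """

    n_per_genotype: int = 60
    pop_means: tuple[Sequence[float], Sequence[float]] = ((15.0, 10.0, 5.0),
                                                          (30.0, 25.0, 20.0))
    pooled_mean: float = 18.0
    residual_sd: float = 2.0
    exact: bool = True

    def __post_init__(self) -> None:
        if self.n_per_genotype < 1:
            raise ValueError("n_per_genotype must be positive")
        if len(self.pop_means) != 2 or any(len(m) != 3 for m in self.pop_means):
            raise ValueError("pop_means must be two sequences of three genotype means")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")


def solve_simpson_design(design: SimpsonDesign) -> dict:
    """Solve for per-(population × genotype) cell counts.

    For each genotype ``g`` the mixing weight ``w`` solves
    ``w * m1[g] + (1 - w) * m2[g] = pooled_mean``; the cell counts are
    ``c1 = w * n`` and ``c2 = n - c1`` and must be non-negative integers.

    Returns a dict with keys ``counts`` (2×3 array, populations × genotypes)
    and ``pop_totals`` (length-2 array).

    Raises
    ------
    DesignInfeasibleError
        If any weight falls outside [0, 1] or any implied count is not an
        integer (within 1e-9 of one).
    """
    m1, m2 = (np.asarray(m, dtype=float) for m in design.pop_means)
    n = design.n_per_genotype
    counts = np.zeros((2, 3), dtype=int)
    for g in range(3):
        if m1[g] == m2[g]:
            if design.pooled_mean != m1[g]:
                raise DesignInfeasibleError(
                    f"genotype {g}: pooled mean {design.pooled_mean} unreachable "
                    f"from equal population means {m1[g]}"
                )
            w = 1.0  # any split works; put everyone in population 1
        else:
            w = (design.pooled_mean - m2[g]) / (m1[g] - m2[g])
        if not 0.0 <= w <= 1.0:
            raise DesignInfeasibleError(
                f"genotype {g}: pooled mean {design.pooled_mean} lies outside "
                f"the span of population means ({m1[g]}, {m2[g]})"
            )
        c1 = w * n
        if abs(c1 - round(c1)) > 1e-9:
            raise DesignInfeasibleError(
                f"genotype {g}: weight {w} implies non-integer cell count {c1} "
                f"for n_per_genotype={n}"
            )
        counts[0, g] = int(round(c1))
        counts[1, g] = n - counts[0, g]
    return {"counts": counts, "pop_totals": counts.sum(axis=1)}


def _exact_noise(rng: np.random.Generator, size: int, sd: float) -> np.ndarray:
    """Zero-mean noise with sample sd exactly ``sd`` (ddof=1)."""
    if sd == 0.0:
        return np.zeros(size)
    if size == 1:
        raise ValueError(
            "a cell of size 1 cannot be centered and rescaled; "
            "increase n_per_genotype or use noisy mode (exact=False)"
        )
    e = rng.standard_normal(size)
    e -= e.mean()
    s = e.std(ddof=1)
    if s == 0.0:  # pragma: no cover - essentially impossible
        e = np.linspace(-1, 1, size)
        e -= e.mean()
        s = e.std(ddof=1)
    return e * (sd / s)


def make_simpson_dataset(design: SimpsonDesign, seed: int | None = 0) -> pd.DataFrame:
    """Generate the Simpson-masking dataset.

    Returns a DataFrame with columns ``individual``, ``population`` (``pop1``
    / ``pop2``), ``genotype`` (0/1/2) and ``expression``.  In exact mode each
    population × genotype cell mean equals its nominal mean to floating
    precision, every pooled genotype mean equals ``pooled_mean`` and the
    pooled regression slope of expression on genotype is exactly zero.
    """
    sol = solve_simpson_design(design)
    rng = np.random.default_rng(seed)
    rows: list[pd.DataFrame] = []
    for p, pop_name in enumerate(("pop1", "pop2")):
        means = np.asarray(design.pop_means[p], dtype=float)
        for g in range(3):
            c = int(sol["counts"][p, g])
            if c == 0:
                continue
            if design.exact:
                expr = means[g] + _exact_noise(rng, c, design.residual_sd)
            else:
                expr = means[g] + design.residual_sd * rng.standard_normal(c)
            rows.append(pd.DataFrame({
                "population": pop_name,
                "genotype": g,
                "expression": expr,
            }))
    out = pd.concat(rows, ignore_index=True)
    out.insert(0, "individual", [f"S{i:04d}" for i in range(len(out))])
    return out


# ---------------------------------------------------------------------------
# Non-transitive correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NonTransitivityDesign:
    """Design for a dataset with a prescribed correlation matrix over
    (allele count, RNA1, RNA2).

    Defaults reproduce the canonical triple r(g, RNA1) = 0.472,
    r(RNA1, RNA2) = 0.508, r(g, RNA2) = −0.471 with 20 individuals per
    genotype.
    """

    n_per_genotype: int = 20
    r_g_rna1: float = 0.472
    r_rna1_rna2: float = 0.508
    r_g_rna2: float = -0.471
    exact: bool = True
    rna1_loc: float = 10.0
    rna1_scale: float = 2.0
    rna2_loc: float = 10.0
    rna2_scale: float = 2.0

    @property
    def target_corr(self) -> np.ndarray:
        """3×3 target correlation matrix ordered (genotype, rna1, rna2)."""
        r1, r12, r2 = self.r_g_rna1, self.r_rna1_rna2, self.r_g_rna2
        return np.array([[1.0, r1, r2], [r1, 1.0, r12], [r2, r12, 1.0]])

    def coefficients(self) -> tuple[float, float, float]:
        """Gram–Schmidt coefficients (alpha, beta, gamma) of RNA2 on the
        orthonormal basis (standardized genotype, RNA1 residual direction,
        fresh orthogonal direction).

        Raises :class:`DesignInfeasibleError` when the target matrix is not
        positive definite (gamma^2 < 0).
        """
        r1, r12, r2 = self.r_g_rna1, self.r_rna1_rna2, self.r_g_rna2
        if not (abs(r1) < 1 and abs(r12) <= 1 and abs(r2) <= 1):
            raise DesignInfeasibleError("correlations must lie in (-1, 1)")
        alpha = r2
        beta = (r12 - r1 * r2) / np.sqrt(1.0 - r1 * r1)
        gamma_sq = 1.0 - alpha * alpha - beta * beta
        if gamma_sq < -1e-12:
            raise DesignInfeasibleError(
                f"target correlations are not jointly feasible (gamma^2 = {gamma_sq:.4g} < 0)"
            )
        return float(alpha), float(beta), float(np.sqrt(max(gamma_sq, 0.0)))


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def make_nontransitivity_dataset(design: NonTransitivityDesign,
                                 seed: int | None = 0) -> pd.DataFrame:
    """Generate the non-transitive-correlation dataset.

    Construction (exact mode): center and normalize the fixed genotype
    vector g-hat; draw u1 unit-norm, centered, orthogonal to g-hat; set
    ``rna1* = r_g1 * g-hat + sqrt(1 - r_g1^2) * u1``; then
    ``rna2* = alpha * g-hat + beta * u1 + gamma * u2`` with u2 centered and
    orthogonal to both and (alpha, beta, gamma) from
    :meth:`NonTransitivityDesign.coefficients`.  Because all basis vectors
    are centered and orthonormal, the empirical sample correlations equal
    the targets exactly.  The RNA columns are then shifted/scaled to the
    design's location/scale (which leaves correlations unchanged).

    In noisy mode the same linear combination is applied to independent
    standard-normal innovations, so correlations match only in expectation.
    """
    n = 3 * design.n_per_genotype
    if design.n_per_genotype < 2:
        raise ValueError("need at least 2 individuals per genotype")
    alpha, beta, gamma = design.coefficients()
    r1 = design.r_g_rna1
    rng = np.random.default_rng(seed)
    g = np.repeat([0.0, 1.0, 2.0], design.n_per_genotype)

    if design.exact:
        ghat = _unit(g - g.mean())
        ones = np.ones(n)

        def fresh_orthogonal(*basis: np.ndarray) -> np.ndarray:
            for _ in range(100):
                u = rng.standard_normal(n)
                u -= u.mean()
                for b in basis:
                    u -= (u @ b) * b
                norm = np.linalg.norm(u)
                if norm > 1e-8:
                    return u / norm
            raise RuntimeError("failed to draw an orthogonal direction")

        u1 = fresh_orthogonal(ghat)
        rna1 = r1 * ghat + np.sqrt(1.0 - r1 * r1) * u1
        u2 = fresh_orthogonal(ghat, u1)
        rna2 = alpha * ghat + beta * u1 + gamma * u2
        # standardize to sample sd 1 before applying the display scale
        rna1 = rna1 / rna1.std(ddof=1)
        rna2 = rna2 / rna2.std(ddof=1)
    else:
        zg = (g - g.mean()) / g.std(ddof=0)
        e1 = rng.standard_normal(n)
        e2 = rng.standard_normal(n)
        rna1 = r1 * zg + np.sqrt(1.0 - r1 * r1) * e1
        rna2 = alpha * zg + beta * e1 + gamma * e2

    rna1 = design.rna1_loc + design.rna1_scale * rna1
    rna2 = design.rna2_loc + design.rna2_scale * rna2
    return pd.DataFrame({
        "individual": [f"S{i:04d}" for i in range(n)],
        "genotype": g.astype(int),
        "rna1": rna1,
        "rna2": rna2,
    })


# ---------------------------------------------------------------------------
# Multi-population cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationSpec:
    """One population: label, cohort size, risk-allele frequency and
    baseline expression of the host transcript and miRNA."""

    name: str
    size: int
    allele_freq: float
    host_baseline: float = 10.0
    mir_baseline: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.allele_freq <= 1.0:
            raise ValueError(f"allele frequency outside [0,1]: {self.allele_freq}")
        if self.size < 1:
            raise ValueError("population size must be positive")


def _default_populations() -> tuple[PopulationSpec, ...]:
    # Five LCL panels; the risk allele is common in the four European
    # populations (0.86) and less common in the African population (0.40);
    # baselines differ between populations (the population main effect).
    return (
        PopulationSpec("CEU", 92, 0.86, host_baseline=10.0, mir_baseline=3.0),
        PopulationSpec("FIN", 95, 0.86, host_baseline=10.5, mir_baseline=3.2),
        PopulationSpec("GBR", 96, 0.86, host_baseline=9.5, mir_baseline=2.8),
        PopulationSpec("TSI", 93, 0.86, host_baseline=10.2, mir_baseline=3.1),
        PopulationSpec("YRI", 89, 0.40, host_baseline=12.0, mir_baseline=3.6),
    )


@dataclass(frozen=True)
class CohortDesign:
    """Multi-population cohort with one cis-variant affecting a host
    transcript and an intronic miRNA in (by default) opposite directions.

    The two molecules share a per-sample multiplicative expression factor
    (lognormal with sigma ``shared_scale_sd``) representing their common
    primary transcript / library-size variation; independent Gaussian noise
    is added on top.  miRNA measurements are zero-inflated: an independent
    Bernoulli dropout mask zeroes a fraction ``mir_dropout`` of samples
    (default 0.403, i.e. ~59.7% of samples detected), and negative latent
    values are clipped to zero.
    """

    populations: tuple[PopulationSpec, ...] = field(default_factory=_default_populations)
    slope_host: float = -1.0
    slope_mir: float = 0.8
    host_sd: float = 1.2
    mir_sd: float = 1.0
    shared_scale_sd: float = 0.25
    mir_dropout: float = 0.403

    def __post_init__(self) -> None:
        if not 0.0 <= self.mir_dropout < 1.0:
            raise ValueError("mir_dropout must lie in [0, 1)")
        if min(self.host_sd, self.mir_sd, self.shared_scale_sd) < 0:
            raise ValueError("noise scales must be non-negative")

    @property
    def n_samples(self) -> int:
        return sum(p.size for p in self.populations)


def null_cohort_design() -> CohortDesign:
    """Fully null cohort design for calibration studies: zero genotype
    slopes and equal expression baselines across populations.

    Note that zero slopes alone do not make the *pooled* regression null:
    with population-specific baselines and allele frequencies the pooled
    test is confounded by construction (the Simpson-like masking scenario),
    so its p-values are not uniform.  Calibration of the tests themselves
    therefore requires removing the population effect on expression as
    well.
    """
    pops = tuple(
        PopulationSpec(p.name, p.size, p.allele_freq,
                       host_baseline=10.0, mir_baseline=3.0)
        for p in _default_populations())
    return CohortDesign(populations=pops, slope_host=0.0, slope_mir=0.0)


def planted_scan_design() -> CohortDesign:
    """Cohort design with a strong planted opposite-sign eQTL.

    The default design mirrors the marginal effect sizes typical of real
    miR-eQTLs, where the zero-inflated miRNA association hovers around the
    significance boundary.  Planted-truth recovery experiments need an
    effect that is unambiguously present, so this design raises the miRNA
    slope until the population-adjusted miRNA correlation is ~0.2 after
    dropout (per-allele slope 2.0 on the normalized-count scale) and the
    host slope to -1.2, leaving all cohort-structure parameters (sizes,
    allele frequencies, baselines, dropout) at their defaults.
    """
    return CohortDesign(slope_host=-1.2, slope_mir=2.0)


def pcr_cohort_design() -> CohortDesign:
    """Cohort design emulating a PCR-quantified cohort: every sample
    detected (no dropout), weak opposite single-feature effects, and a
    large shared expression factor — the regime in which the miRNA/host
    ratio is a more powerful readout of processing than either transcript
    alone, because the ratio cancels the shared factor exactly.
    """
    return CohortDesign(slope_host=-0.5, slope_mir=0.5, shared_scale_sd=0.5,
                        mir_dropout=0.0)


def simulate_cohort(design: CohortDesign, seed: int | None = 0) -> dict:
    """Simulate genotypes, host-gene expression and miRNA counts.

    Returns a dict with keys:

    ``genotypes``
        DataFrame (samples × 1 variant, column ``snp1``) of 0/1/2 counts
        drawn Binomial(2, freq) within each population (Hardy–Weinberg).
    ``host``
        DataFrame (samples × 1) of linear-scale host-transcript levels.
    ``mir``
        DataFrame (samples × 1) of non-negative miRNA normalized counts
        with exact zeros for dropouts.
    ``metadata``
        DataFrame with ``sample`` and ``population`` columns.
    """
    rng = np.random.default_rng(seed)
    pops, gt, host, mir = [], [], [], []
    for spec in design.populations:
        g = rng.binomial(2, spec.allele_freq, size=spec.size).astype(float)
        shared = np.exp(design.shared_scale_sd * rng.standard_normal(spec.size))
        h = shared * (spec.host_baseline + design.slope_host * g
                      + design.host_sd * rng.standard_normal(spec.size))
        m_latent = shared * (spec.mir_baseline + design.slope_mir * g
                             + design.mir_sd * rng.standard_normal(spec.size))
        keep = rng.random(spec.size) >= design.mir_dropout
        m = np.where(keep, np.maximum(m_latent, 0.0), 0.0)
        pops.extend([spec.name] * spec.size)
        gt.append(g)
        host.append(h)
        mir.append(m)
    samples = [f"S{i:04d}" for i in range(design.n_samples)]
    index = pd.Index(samples, name="sample")
    return {
        "genotypes": pd.DataFrame({"snp1": np.concatenate(gt)}, index=index),
        "host": pd.DataFrame({"host": np.concatenate(host)}, index=index),
        "mir": pd.DataFrame({"mir": np.concatenate(mir)}, index=index),
        "metadata": pd.DataFrame({"sample": samples, "population": pops}).set_index("sample"),
    }


def write_dataset(table: pd.DataFrame, path: str | Path, design, seed) -> None:
    """Write a generated dataset as TSV plus a JSON sidecar recording the
    design parameters and seed."""
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    payload = {"design": asdict(design) if hasattr(design, "__dataclass_fields__") else design,
               "seed": seed}
    sidecar.write_text(json.dumps(payload, indent=2, default=str) + "\n")
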