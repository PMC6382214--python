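"""Paradox taxonomy for population-structured eQTL results.

Three phenomena are classified, each from statistics already computed by
the association panel:

* **Simpson-like masking** — the genotype effect is significant once the
  population structure is adjusted for (ANCOVA) but invisible in the pooled
  regression (SLR).  A *reversal* additionally flips the pooled slope sign
  against the common within-population sign.
* **Non-transitivity of correlation** — the variant correlates with the
  miRNA and with the host transcript in opposite directions even though the
  two transcripts are positively correlated with each other (they share a
  primary transcript).
* **Uncoupling** — the variant's correlation with the mature miRNA diverges
  from its correlation with the host transcript by more than a threshold
  (default 0.2), suggesting that stem-loop processing rather than
  transcription drives the miR-eQTL.

All correlations fed to the detectors should be population-adjusted
(:func:`mireqtl.stats.partial_pearson`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .stats import TestResult

__all__ = ["ParadoxFlags", "detect_simpson", "detect_nontransitivity",
           "uncoupling_score", "classify"]

UNCOUPLING_THRESHOLD = 0.2


@dataclass(frozen=True)
class ParadoxFlags:
    """Classification of one locus, with the correlation triple that drove it."""

    simpson_category: str  # "masked" | "reversal" | "none"
    non_transitive: bool
    uncoupled: bool
    r_mir_snp: float
    r_host_snp: float
    r_mir_host: float
    uncoupling_score: float

    @property
    def simpson_like(self) -> bool:
        return self.simpson_category != "none"


def detect_simpson(slr: TestResult, ancova_genotype: TestResult,
                   per_population_slopes=None, alpha: float = 0.05) -> str:
    """Classify Simpson-like behavior from the SLR/ANCOVA pair.

    Returns ``"masked"`` when the population-adjusted genotype effect is
    significant but the pooled one is not; ``"reversal"`` when additionally
    the pooled slope sign opposes the (shared) sign of every per-population
    slope; ``"none"`` otherwise.
    """
    if ancova_genotype is None:
        raise ValueError("ANCOVA genotype result is required")
    masked = ancova_genotype.p_value < alpha and slr.p_value >= alpha
    if not masked:
        return "none"
    if per_population_slopes is not None and slr.estimate is not None:
        signs = {math.copysign(1.0, s) for s in per_population_slopes if s != 0}
        pooled = slr.estimate
        if len(signs) == 1 and pooled != 0 and math.copysign(1.0, pooled) not in signs:
            return "reversal"
    return "masked"


def detect_nontransitivity(r_mir_snp: float, r_host_snp: float,
                           r_mir_host: float,
                           require_positive_coupling: bool = True) -> bool:
    """Flag asynchronous correlation directions across the SNP/miRNA/host triple.

    True iff the SNP correlates with the miRNA and the host transcript in
    opposite directions while (by default) the two transcripts themselves
    are positively correlated.  A correlation of exactly zero has no sign
    and never fires the detector.
    """
    if r_mir_snp == 0.0 or r_host_snp == 0.0:
        return False
    opposite = (r_mir_snp > 0) != (r_host_snp > 0)
    if require_positive_coupling:
        return opposite and r_mir_host > 0.0
    return opposite


def uncoupling_score(r_mir_snp: float, r_host_snp: float,
                     threshold: float = UNCOUPLING_THRESHOLD) -> tuple[float, bool]:
    """Absolute divergence of the two SNP correlations; flag iff strictly
    above the threshold."""
    for r in (r_mir_snp, r_host_snp):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"correlation outside [-1, 1]: {r}")
    score = abs(r_mir_snp - r_host_snp)
    return score, score > threshold


def classify(*, mir_slr: TestResult, mir_ancova_genotype: TestResult,
             r_mir_snp: float, r_host_snp: float, r_mir_host: float,
             per_population_slopes=None, alpha: float = 0.05,
             uncoupling_threshold: float = UNCOUPLING_THRESHOLD,
             require_positive_coupling: bool = True) -> ParadoxFlags:
    """Run all three detectors for one locus and bundle the flags."""
    category = detect_simpson(mir_slr, mir_ancova_genotype,
                              per_population_slopes, alpha)
    nt = detect_nontransitivity(r_mir_snp, r_host_snp, r_mir_host,
                                require_positive_coupling)
    score, flag = uncoupling_score(r_mir_snp, r_host_snp, uncoupling_threshold)
    return ParadoxFlags(simpson_category=category, non_transitive=nt,
                        uncoupled=flag, r_mir_snp=r_mir_snp,
                        r_host_snp=r_host_snp, r_mir_host=r_mir_host,
                        uncoupling_score=score)
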