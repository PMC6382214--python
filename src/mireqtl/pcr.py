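"""Relative quantification of real-time PCR and dual-luciferase reporter data.

Implements the standard threshold-cycle arithmetic:

* triplicate aggregation (mean or median) with an undetected-well floor of
  Ct = 45;
* the dCt method: ``rel_expr = 2^-(Ct_target - Ct_reference) * scale`` with
  a cosmetic default scale of 1000;
* the ddCt allele/condition comparison
  ``2^-[(Ct_miR - Ct_refmiR) - (Ct_precursor - Ct_refgene)]`` with an
  explicit rescaling baseline;
* signed linear fold-changes (downregulation reported as ``-1/ratio``);
* GLuc/SEAP reporter normalization against a control-3'UTR cotransfection
  with percent change versus a scrambled-sequence condition and a Welch
  t-test across biological replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as st
from .stats import TestResult

__all__ = ["CT_FLOOR", "QuantResult", "ReporterResult", "load_ct_table",
           "aggregate_ct", "delta_ct_expression", "delta_delta_ct",
           "rescale_to_baseline", "fold_change", "reporter_normalize"]

CT_FLOOR = 45.0


@dataclass(frozen=True)
class QuantResult:
    """Linear-scale relative expression of one assay in one sample."""

    sample: str
    target_assay: str
    reference_assay: str
    delta_ct: float
    rel_expr: float
    at_detection_limit: bool = False


@dataclass(frozen=True)
class ReporterResult:
    """Normalized reporter readout for one 3'UTR construct and condition."""

    construct: str
    condition: str
    gluc_seap_ratio: float
    normalized_ratio: float
    percent_change: float | None
    welch: TestResult | None


def load_ct_table(rows: pd.DataFrame) -> pd.DataFrame:
    """Validate and floor a well-level Ct table.

    Expects columns ``sample``, ``assay``, ``replicate``, ``ct`` and an
    optional boolean ``detected``; undetected wells are set to the
    Ct = 45 floor.  Returns a copy with a ``detected`` column present.
    """
    required = {"sample", "assay", "replicate", "ct"}
    missing = required - set(rows.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns: {sorted(missing)}")
    out = rows.copy()
    if "detected" not in out.columns:
        out["detected"] = out["ct"] < CT_FLOOR
    out["detected"] = out["detected"].astype(bool)
    out.loc[~out["detected"], "ct"] = CT_FLOOR
    bad = out[(out["ct"] <= 0) | (out["ct"] > CT_FLOOR)]
    if len(bad):
        raise ValueError(f"Ct values outside (0, {CT_FLOOR}]: {bad['ct'].tolist()[:5]}")
    return out


def aggregate_ct(table: pd.DataFrame, method: str = "mean") -> pd.DataFrame:
    """Aggregate well replicates per (sample, assay).

    ``method`` is ``"mean"`` (cohort dCt convention) or ``"median"``
    (allele-comparison convention).  The Ct = 45 floor is applied to
    undetected wells before aggregating.  Returns a frame with columns
    ``sample``, ``assay``, ``ct``, ``n_wells``, ``any_floored``.
    """
    if method not in ("mean", "median"):
        raise ValueError(f"unknown aggregation method: {method}")
    table = load_ct_table(table)
    grouped = table.groupby(["sample", "assay"], sort=False)
    if not len(table):
        raise ValueError("empty Ct table")
    agg = grouped.agg(ct=("ct", method), n_wells=("ct", "size"),
                      any_floored=("detected", lambda d: bool((~d).any())))
    return agg.reset_index()


def delta_ct_expression(ct_target: float, ct_reference: float, *,
                        sample: str = "", target_assay: str = "",
                        reference_assay: str = "", scale: float = 1000.0,
                        at_detection_limit: bool = False) -> QuantResult:
    """dCt relative expression: ``2^-(Ct_target - Ct_ref) * scale``."""
    if ct_target is None or ct_reference is None or \
            np.isnan(ct_target) or np.isnan(ct_reference):
        raise ValueError("both target and reference Ct must be present")
    dct = float(ct_target) - float(ct_reference)
    flagged = at_detection_limit or ct_target >= CT_FLOOR or ct_reference >= CT_FLOOR
    return QuantResult(sample=sample, target_assay=target_assay,
                       reference_assay=reference_assay, delta_ct=dct,
                       rel_expr=float(2.0 ** (-dct) * scale),
                       at_detection_limit=bool(flagged))


def delta_delta_ct(ct_mir: float, ct_ref_mir: float,
                   ct_precursor: float, ct_ref_gene: float) -> float:
    """ddCt ratio of mature-miRNA output per precursor transcript.

    ``ddCt = (Ct_miR - Ct_refmiR) - (Ct_precursor - Ct_refgene)``;
    returns ``2^-ddCt``.  Invariant to adding a constant to all four Cts
    (plate-shift invariance).
    """
    cts = [ct_mir, ct_ref_mir, ct_precursor, ct_ref_gene]
    if any(c is None or np.isnan(c) for c in cts):
        raise ValueError("all four Ct components must be present")
    ddct = (ct_mir - ct_ref_mir) - (ct_precursor - ct_ref_gene)
    return float(2.0 ** (-ddct))


def rescale_to_baseline(values: pd.Series, baseline_key) -> pd.Series:
    """Divide a series of linear ratios by a designated baseline entry so
    the baseline condition equals 1."""
    base = values.loc[baseline_key]
    if isinstance(base, pd.Series):
        base = base.iloc[0]
    if base <= 0:
        raise ValueError("baseline ratio must be positive")
    return values / base


def fold_change(mean_a: float, mean_b: float) -> float:
    """Signed linear fold-change of a versus b.

    ``ratio = a / b``; ratios below 1 (downregulation in a) are inverted
    and negated, so |fold-change| >= 1 always and the sign carries the
    direction.
    """
    if mean_a <= 0 or mean_b <= 0:
        raise ValueError("fold change requires strictly positive means")
    ratio = mean_a / mean_b
    return float(ratio) if ratio >= 1.0 else float(-1.0 / ratio)


def reporter_normalize(rows: pd.DataFrame, control_construct: str,
                       scrambled_condition: str) -> list[ReporterResult]:
    """Normalize dual-luciferase reporter data.

    ``rows`` has columns ``construct`` (3'UTR plasmid id), ``condition``
    (cotransfected miRNA plasmid: the miRNA or the scrambled control),
    ``replicate`` (biological replicate id), ``gluc`` and ``seap``
    (luminescence reads; duplicate reads per well appear as extra rows and
    are averaged).

    Per biological replicate the GLuc/SEAP ratio is computed from averaged
    reads; per (construct, condition) the mean ratio is normalized to the
    control-3'UTR construct under the same condition.  For non-scrambled
    conditions the percent change versus the scrambled condition of the
    same construct is reported together with a Welch t-test across the
    per-replicate normalized ratios.
    """
    required = {"construct", "condition", "replicate", "gluc", "seap"}
    missing = required - set(rows.columns)
    if missing:
        raise ValueError(f"reporter table lacks columns: {sorted(missing)}")
    if control_construct not in set(rows["construct"]):
        raise ValueError(f"control construct '{control_construct}' absent from data")
    wells = rows.groupby(["construct", "condition", "replicate"], sort=False)[
        ["gluc", "seap"]].mean().reset_index()
    if (wells["seap"] <= 0).any():
        raise ValueError("SEAP luminescence must be positive")
    wells["ratio"] = wells["gluc"] / wells["seap"]

    # per-replicate normalization to the control 3'UTR under the same condition
    ctrl = wells[wells["construct"] == control_construct] \
        .groupby("condition")["ratio"].mean()
    if (ctrl <= 0).any():
        raise ValueError("control-construct ratio must be positive")
    wells["norm_ratio"] = wells.apply(
        lambda r: r["ratio"] / ctrl.loc[r["condition"]], axis=1)

    results: list[ReporterResult] = []
    for (construct, condition), grp in wells.groupby(["construct", "condition"],
                                                     sort=False):
        mean_ratio = float(grp["ratio"].mean())
        mean_norm = float(grp["norm_ratio"].mean())
        pct = None
        welch = None
        if condition != scrambled_condition:
            scr = wells[(wells["construct"] == construct)
                        & (wells["condition"] == scrambled_condition)]
            if len(scr):
                scr_norm = float(scr["norm_ratio"].mean())
                if scr_norm == 0:
                    raise ValueError("scrambled-condition ratio is zero")
                pct = (mean_norm / scr_norm - 1.0) * 100.0
                if len(grp) >= 2 and len(scr) >= 2:
                    a = grp["norm_ratio"].to_numpy()
                    b = scr["norm_ratio"].to_numpy()
                    if not (np.ptp(a) == 0 and np.ptp(b) == 0):
                        welch = st.welch_t(a, b)
        results.append(ReporterResult(construct=construct, condition=condition,
                                      gluc_seap_ratio=mean_ratio,
                                      normalized_ratio=mean_norm,
                                      percent_change=pct, welch=welch))
    return results
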