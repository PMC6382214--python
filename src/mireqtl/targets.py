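"""Candidate-target screening and prioritization for a miRNA
over-expression experiment.

The module consumes an externally produced differential-expression table
(probe-set level: signed linear fold-changes, p-values, group mean log2
signals, optional hybridization energy and prediction-consensus columns)
and applies the screening rules:

* candidate filter: downregulated with ``p < 0.05`` (strict) and
  ``fold_change <= -1.5`` (inclusive) at a given time point;
* prioritization: nominally downregulated at both time points, robustly
  expressed in the control condition (mean log2 signal > 10) and, where a
  minimum-free-energy column is available, a predicted 3'UTR duplex with
  ``mfe <= -15`` kcal/mol; ranked by the 24 h fold-change;
* consensus gate: predicted by at least 6 of 12 target-prediction
  algorithms.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["filter_candidates", "prioritize", "consensus_gate"]

ALPHA = 0.05
FC_CUT = -1.5
EXPR_GATE_LOG2 = 10.0
MFE_CUT = -15.0


def _require(records: pd.DataFrame, cols: set[str]) -> None:
    missing = cols - set(records.columns)
    if missing:
        raise ValueError(f"DE table lacks columns: {sorted(missing)}")


def filter_candidates(records: pd.DataFrame, *, p_col: str = "p_value",
                      fc_col: str = "fold_change", alpha: float = ALPHA,
                      fc_cut: float = FC_CUT) -> pd.DataFrame:
    """Keep probe sets with ``p < alpha`` (strict) and signed linear
    ``fold_change <= fc_cut`` (inclusive boundary)."""
    _require(records, {p_col, fc_col})
    keep = (records[p_col] < alpha) & (records[fc_col] <= fc_cut)
    return records.loc[keep].copy()


def _nominally_down(records: pd.DataFrame, p_col: str, fc_col: str,
                    strict_fc: bool, alpha: float) -> pd.Series:
    # loose reading: nominal significance with any downregulation (fc < -1);
    # strict reading: the full fold-change cut at this time point too
    down = records[fc_col] <= FC_CUT if strict_fc else records[fc_col] < -1.0
    return (records[p_col] < alpha) & down


def prioritize(records: pd.DataFrame, *, p_24h: str = "p_24h",
               fc_24h: str = "fc_24h", p_48h: str = "p_48h",
               fc_48h: str = "fc_48h", expr_col: str = "control_log2_mean",
               mfe_col: str = "mfe", strict_both_timepoints: bool = False,
               alpha: float = ALPHA) -> pd.DataFrame:
    """Rank probable direct targets.

    Requirements: nominal downregulation at 24 h and 48 h (see
    ``strict_both_timepoints`` for whether the full fold-change cut applies
    at both times or only nominal significance with a negative fold-change),
    control-condition mean log2 signal above 10 and, when an ``mfe`` column
    is present, a hybridization energy at or below −15 kcal/mol.  The
    result is sorted by the 24 h fold-change (most downregulated first).
    """
    _require(records, {p_24h, fc_24h, p_48h, fc_48h, expr_col})
    keep = (_nominally_down(records, p_24h, fc_24h, strict_both_timepoints, alpha)
            & _nominally_down(records, p_48h, fc_48h, strict_both_timepoints, alpha)
            & (records[expr_col] > EXPR_GATE_LOG2))
    if mfe_col in records.columns:
        keep &= records[mfe_col] <= MFE_CUT
    out = records.loc[keep].copy()
    return out.sort_values(fc_24h, ascending=True)


def consensus_gate(records: pd.DataFrame, *, consensus_col: str = "prediction_consensus",
                   min_algorithms: int = 6) -> pd.Series:
    """Boolean flag per record: predicted by at least ``min_algorithms`` of
    the target-prediction algorithms; missing counts default to False."""
    _require(records, {consensus_col})
    vals = records[consensus_col]
    if vals.isna().any():
        warnings.warn("missing prediction-consensus values treated as below threshold",
                      stacklevel=2)
    return (vals >= min_algorithms).fillna(False).astype(bool)
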