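"""Genome-wide cis-miR-eQTL scan over miRNA stem-loop regions.

The scan takes a cohort (genotypes, mature-miRNA expression, host-gene
expression, population metadata) and a set of annotated stem-loops, keeps
biallelic SNPs inside each stem-loop or within a flank window (default
25 bases) on either side, runs the full association panel for the mature
miRNA and its host transcript, retains pairs whose miRNA ANCOVA genotype
effect clears alpha, and attaches the paradox flags computed from
population-adjusted correlations.

Coordinates are 0-based half-open internally; variant positions arrive
1-based (VCF convention) and are converted at the boundary.  Relative
position labels follow the report convention: ``P`` inside the precursor,
``+k`` / ``-k`` for k bases downstream / upstream of the stem-loop in
transcription orientation (strand-aware).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import paradox as px
from .eqtl import EqtlResults, run_eqtl
from .stats import DegenerateInputError

__all__ = ["StemLoop", "ScanConfig", "ScanRow", "filter_stem_loop_snps",
           "annotate_relative_position", "scan", "scan_to_frame"]

log = logging.getLogger(__name__)

_AUTOSOMES = {str(i) for i in range(1, 23)}


@dataclass(frozen=True)
class StemLoop:
    """A miRNA precursor hairpin locus (0-based half-open coordinates)."""

    mir_id: str
    chrom: str
    start: int
    end: int
    strand: str
    host_gene: str | None = None
    mature_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.mir_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.mir_id}: strand must be '+' or '-'")


@dataclass(frozen=True)
class ScanConfig:
    """Scan parameters.

    ``flank`` — bases beyond the stem-loop on each side (default 25);
    ``alpha`` — significance level for retention (default 0.05);
    ``uncoupling_threshold`` — minimum |r_miR,SNP − r_host,SNP| to call
    uncoupling (default 0.2); ``interaction`` / ``lmm`` toggle the
    genotype-by-population term and the mixed-model panel;
    ``autosomes_only`` restricts to chromosomes 1–22.
    """

    flank: int = 25
    alpha: float = 0.05
    uncoupling_threshold: float = 0.2
    interaction: bool = False
    lmm: bool = False
    autosomes_only: bool = True
    require_positive_coupling: bool = True

    def __post_init__(self) -> None:
        if self.flank < 0:
            raise ValueError("flank must be non-negative")


@dataclass(frozen=True)
class ScanRow:
    """One retained (variant, mature miRNA) association."""

    mir_id: str
    host_gene: str
    variant_id: str
    chrom: str
    pos: int  # 1-based variant position
    relative_position: str
    mir_result: EqtlResults
    host_result: EqtlResults
    flags: px.ParadoxFlags


def _norm_chrom(c: str) -> str:
    return c[3:] if c.lower().startswith("chr") else c


def _is_biallelic_snv(ref: str, alt) -> bool:
    alts = alt if isinstance(alt, (list, tuple)) else [alt]
    return len(alts) == 1 and len(ref) == 1 and len(alts[0]) == 1 \
        and ref != "." and alts[0] not in (".", "*")


def filter_stem_loop_snps(variants: pd.DataFrame, stem_loops: list[StemLoop],
                          config: ScanConfig | None = None) -> list[tuple[str, StemLoop]]:
    """Select biallelic SNVs within each stem-loop ± flank window.

    ``variants`` needs columns ``id``, ``chrom``, ``pos`` (1-based), ``ref``,
    ``alt``.  A variant at 0-based position p is kept for a stem-loop when
    ``start - flank <= p < end + flank``; multiallelic records and indels
    are dropped (counted in the log).  Returns (variant id, stem-loop)
    pairs.
    """
    config = config or ScanConfig()
    required = {"id", "chrom", "pos", "ref", "alt"}
    missing = required - set(variants.columns)
    if missing:
        raise ValueError(f"variant table lacks columns: {sorted(missing)}")
    v_chroms = {_norm_chrom(str(c)) for c in variants["chrom"].unique()}
    s_chroms = {_norm_chrom(s.chrom) for s in stem_loops}
    if stem_loops and len(variants) and not (v_chroms & s_chroms):
        raise ValueError(
            "no chromosome shared between variants and stem-loops "
            f"({sorted(v_chroms)[:5]} vs {sorted(s_chroms)[:5]}); check "
            "whether one file uses 'chr' prefixes and the other does not")
    dropped_nonsnv = 0
    pairs: list[tuple[str, StemLoop]] = []
    for row in variants.itertuples(index=False):
        chrom = _norm_chrom(str(row.chrom))
        if config.autosomes_only and chrom not in _AUTOSOMES:
            continue
        if not _is_biallelic_snv(str(row.ref), row.alt):
            dropped_nonsnv += 1
            continue
        pos0 = int(row.pos) - 1
        for sl in stem_loops:
            if _norm_chrom(sl.chrom) != chrom:
                continue
            if sl.start - config.flank <= pos0 < sl.end + config.flank:
                pairs.append((str(row.id), sl))
    if dropped_nonsnv:
        log.info("dropped %d non-biallelic-SNV records", dropped_nonsnv)
    return pairs


def annotate_relative_position(pos: int, stem_loop: StemLoop,
                               flank: int | None = None) -> str:
    """Label a variant's position relative to the stem-loop.

    ``pos`` is the 1-based variant position.  Returns ``"P"`` inside the
    precursor, else a signed offset in transcription orientation: on the
    plus strand the genomic right flank is downstream (``+k``); on the
    minus strand the genomic *left* flank is downstream, so signs flip.
    When ``flank`` is given, offsets beyond it raise ValueError.
    """
    pos0 = pos - 1
    if stem_loop.start <= pos0 < stem_loop.end:
        return "P"
    if pos0 >= stem_loop.end:
        k = pos0 - stem_loop.end + 1
        genomic_right = True
    else:
        k = stem_loop.start - pos0
        genomic_right = False
    if flank is not None and k > flank:
        raise ValueError(
            f"position {pos} is {k} bases outside {stem_loop.mir_id}, "
            f"beyond the {flank}-base window")
    downstream = genomic_right if stem_loop.strand == "+" else not genomic_right
    return f"+{k}" if downstream else f"-{k}"


def scan(mir_expr: pd.DataFrame, host_expr: pd.DataFrame,
         genotypes: pd.DataFrame, metadata: pd.DataFrame,
         stem_loops: list[StemLoop], variants: pd.DataFrame,
         config: ScanConfig | None = None,
         mature_map: dict[str, str] | None = None) -> list[ScanRow]:
    """Run the cis-miR-eQTL scan.

    Parameters
    ----------
    mir_expr, host_expr : DataFrame
        samples × features expression (linear scale), indexed by sample id;
        miRNA columns are mature-miRNA ids, host columns host-gene ids.
    genotypes : DataFrame
        samples × variants additive allele counts (NaN = missing), columns
        named by variant id.
    metadata : DataFrame
        Indexed by sample id with a ``population`` column.
    stem_loops, variants
        Annotation inputs for :func:`filter_stem_loop_snps`.
    mature_map : dict, optional
        Maps mature-miRNA expression column -> stem-loop mir_id; defaults
        to testing every ``mature_ids`` entry (or the mir_id itself) that
        appears in ``mir_expr``.

    Returns rows sorted by genomic position; each retained row has the
    mature-miRNA ANCOVA genotype p-value below ``config.alpha``.
    """
    config = config or ScanConfig()
    samples = mir_expr.index.intersection(host_expr.index) \
                       .intersection(genotypes.index).intersection(metadata.index)
    pop = metadata.loc[samples, "population"].to_numpy()
    pairs = filter_stem_loop_snps(variants, stem_loops, config)
    vinfo = variants.set_index("id")
    rows: list[ScanRow] = []
    for variant_id, sl in pairs:
        if variant_id not in genotypes.columns:
            log.warning("variant %s has no genotype column; skipped", variant_id)
            continue
        mature_cols = [m for m in (sl.mature_ids or (sl.mir_id,))
                       if m in mir_expr.columns]
        if mature_map:
            mature_cols = [m for m, s in mature_map.items()
                           if s == sl.mir_id and m in mir_expr.columns]
        if sl.host_gene is None or sl.host_gene not in host_expr.columns:
            log.info("stem-loop %s: no host-gene expression; skipped", sl.mir_id)
            continue
        g = genotypes[variant_id].loc[samples].to_numpy(dtype=float)
        host = host_expr[sl.host_gene].loc[samples].to_numpy(dtype=float)
        pos = int(vinfo.loc[variant_id, "pos"])
        for mature in mature_cols:
            mir = mir_expr[mature].loc[samples].to_numpy(dtype=float)
            try:
                mir_res = run_eqtl(mir, g, pop, feature_id=mature,
                                   variant_id=variant_id,
                                   interaction=config.interaction,
                                   lmm=config.lmm, alpha=config.alpha)
            except DegenerateInputError as exc:
                log.info("pair (%s, %s) skipped: %s", variant_id, mature, exc)
                continue
            if not mir_res.record.ancova.genotype.p_value < config.alpha:
                continue
            try:
                host_res = run_eqtl(host, g, pop, feature_id=sl.host_gene,
                                    variant_id=variant_id,
                                    interaction=config.interaction,
                                    lmm=config.lmm, alpha=config.alpha)
            except DegenerateInputError as exc:
                log.info("host panel for (%s, %s) failed: %s", variant_id, sl.mir_id, exc)
                continue
            from .stats import partial_pearson
            r_mh = partial_pearson(mir, host, pop)
            flags = px.classify(
                mir_slr=mir_res.record.slr,
                mir_ancova_genotype=mir_res.record.ancova.genotype,
                r_mir_snp=mir_res.record.r_adjusted.estimate,
                r_host_snp=host_res.record.r_adjusted.estimate,
                r_mir_host=r_mh.estimate,
                alpha=config.alpha,
                uncoupling_threshold=config.uncoupling_threshold,
                require_positive_coupling=config.require_positive_coupling,
            )
            rows.append(ScanRow(
                mir_id=sl.mir_id, host_gene=sl.host_gene, variant_id=variant_id,
                chrom=_norm_chrom(sl.chrom), pos=pos,
                relative_position=annotate_relative_position(pos, sl),
                mir_result=mir_res, host_result=host_res, flags=flags))
    rows.sort(key=lambda r: (r.chrom.zfill(2) if r.chrom.isdigit() else r.chrom,
                             r.pos, r.mir_id))
    return rows


_REPORT_COLUMNS = [
    "mir_id", "host_gene", "variant_id", "chrom", "pos", "relative_position",
    "mir_slr_p", "mir_ancova_genotype_p", "mir_ancova_population_p",
    "host_slr_p", "host_ancova_genotype_p", "r_mir_snp", "r_host_snp",
    "r_mir_host", "uncoupling_score", "simpson_category", "non_transitive",
    "uncoupled",
]


def scan_to_frame(rows: list[ScanRow]) -> pd.DataFrame:
    """Flatten scan rows into the tabular report layout."""
    if not rows:
        return pd.DataFrame(columns=_REPORT_COLUMNS)
    records = []
    for r in rows:
        mi, ho = r.mir_result.record, r.host_result.record
        rec = {
            "mir_id": r.mir_id, "host_gene": r.host_gene,
            "variant_id": r.variant_id, "chrom": r.chrom, "pos": r.pos,
            "relative_position": r.relative_position,
            "mir_slr_p": mi.slr.p_value,
            "mir_ancova_genotype_p": mi.ancova.genotype.p_value,
            "mir_ancova_population_p": mi.ancova.population.p_value,
            "host_slr_p": ho.slr.p_value,
            "host_ancova_genotype_p": ho.ancova.genotype.p_value,
            "r_mir_snp": r.flags.r_mir_snp, "r_host_snp": r.flags.r_host_snp,
            "r_mir_host": r.flags.r_mir_host,
            "uncoupling_score": r.flags.uncoupling_score,
            "simpson_category": r.flags.simpson_category,
            "non_transitive": r.flags.non_transitive,
            "uncoupled": r.flags.uncoupled,
        }
        if mi.lmm is not None and mi.lmm.genotype_wald is not None:
            rec["mir_lmm_wald_p"] = mi.lmm.genotype_wald.p_value
        records.append(rec)
    return pd.DataFrame.from_records(records)
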