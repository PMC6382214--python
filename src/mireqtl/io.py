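"""Readers and writers for the standard input/output formats.

Genotypes arrive as VCF 4.x (parsed with cyvcf2; additive coding counts the
alternate allele, phase ignored, missing calls become NaN) or as a 0/1/2
TSV with sample rows and variant columns.  Stem-loop annotations arrive as
BED6 (0-based half-open) or GFF3 (1-based closed); both are converted to
the internal 0-based half-open convention at the boundary, and a strand is
mandatory.  Expression and metadata tables are plain TSV.  The scan report
writer produces a deterministic, fixed-precision TSV plus a JSON sidecar
recording configuration, seed and package version.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .scan import ScanConfig, ScanRow, StemLoop, scan_to_frame

log = logging.getLogger(__name__)

__all__ = ["GenotypeMatrix", "read_genotypes", "read_expression",
           "read_metadata", "read_stem_loops", "write_scan_report",
           "load_config"]


@dataclasses.dataclass
class GenotypeMatrix:
    """samples × variants additive allele counts with variant metadata.

    ``values`` is a float DataFrame (NaN for missing calls) whose columns
    are variant ids; ``variants`` holds one row per variant with columns
    ``id``, ``chrom``, ``pos`` (1-based), ``ref``, ``alt``.
    """

    values: pd.DataFrame
    variants: pd.DataFrame


def _read_vcf(path: str | Path, skip_multiallelic: bool = True) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    meta = []
    n_skipped = 0
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            if skip_multiallelic:
                n_skipped += 1
                continue
            raise ValueError(f"multiallelic record at {var.CHROM}:{var.POS}")
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        codes = np.full(len(samples), np.nan)
        for s, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            if len(alleles) == len(gt) - 1 and alleles:
                codes[s] = float(sum(alleles))
        columns[vid] = codes
        meta.append({"id": vid, "chrom": var.CHROM, "pos": var.POS,
                     "ref": var.REF, "alt": var.ALT[0]})
    if n_skipped:
        log.info("skipped %d multiallelic VCF records", n_skipped)
    values = pd.DataFrame(columns, index=pd.Index(samples, name="sample"))
    return GenotypeMatrix(values=values, variants=pd.DataFrame(meta))


def _read_tsv012(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", "."])
    values = df.astype(float)
    bad = values.stack(future_stack=True).dropna()
    if not bad.isin([0.0, 1.0, 2.0]).all():
        raise ValueError("0/1/2 genotype TSV contains values outside {0,1,2,NA}")
    values.index.name = "sample"
    meta = pd.DataFrame({"id": values.columns,
                         "chrom": pd.NA, "pos": pd.NA, "ref": pd.NA, "alt": pd.NA})
    return GenotypeMatrix(values=values, variants=meta)


def read_genotypes(path: str | Path, format: str = "vcf",
                   skip_multiallelic: bool = True) -> GenotypeMatrix:
    """Read genotypes as additive alternate-allele counts.

    ``format`` is ``"vcf"`` or ``"tsv012"``.  In VCF mode phased and
    unphased calls code identically, half-missing and missing calls become
    NaN, and multiallelic records are skipped (logged) or rejected per
    ``skip_multiallelic``.
    """
    if format == "vcf":
        return _read_vcf(path, skip_multiallelic)
    if format == "tsv012":
        return _read_tsv012(path)
    raise ValueError(f"unknown genotype format: {format}")


def read_expression(path: str | Path) -> pd.DataFrame:
    """samples × features TSV, first column = sample id."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata TSV; must contain a ``population`` column."""
    meta = pd.read_csv(path, sep="\t", index_col=0)
    if "population" not in meta.columns:
        raise ValueError("metadata lacks a 'population' column")
    return meta


def read_stem_loops(path: str | Path, format: str = "bed") -> list[StemLoop]:
    """Read stem-loop intervals from BED6 or GFF3.

    BED intervals are 0-based half-open and used as is; GFF3 intervals are
    1-based closed and converted (start-1, end).  The feature name (BED
    column 4 / GFF3 ``ID`` or ``Name`` attribute) becomes the miRNA id and
    an optional ``host_gene`` GFF3 attribute (or BED column 7) the host
    gene.  A missing strand is an error.
    """
    path = Path(path)
    loops: list[StemLoop] = []
    if format == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] < 6:
            raise ValueError("BED input needs at least 6 columns (BED6, strand required)")
        for row in df.itertuples(index=False):
            strand = str(row[5])
            if strand not in ("+", "-"):
                raise ValueError(f"missing/invalid strand for {row[3]}: '{strand}'")
            host = str(row[6]) if df.shape[1] > 6 and not pd.isna(row[6]) else None
            loops.append(StemLoop(mir_id=str(row[3]), chrom=str(row[0]),
                                  start=int(row[1]), end=int(row[2]),
                                  strand=strand, host_gene=host))
    elif format == "gff3":
        names = ["seqid", "source", "type", "start", "end", "score", "strand",
                 "phase", "attributes"]
        df = pd.read_csv(path, sep="\t", header=None, comment="#", names=names)
        for row in df.itertuples(index=False):
            if row.strand not in ("+", "-"):
                raise ValueError(f"missing/invalid strand in GFF3 near {row.seqid}:{row.start}")
            attrs = dict(
                item.split("=", 1) for item in str(row.attributes).split(";") if "=" in item)
            mir_id = attrs.get("ID") or attrs.get("Name")
            if not mir_id:
                raise ValueError("GFF3 feature lacks ID/Name attribute")
            loops.append(StemLoop(mir_id=mir_id, chrom=str(row.seqid),
                                  start=int(row.start) - 1, end=int(row.end),
                                  strand=row.strand,
                                  host_gene=attrs.get("host_gene")))
    else:
        raise ValueError(f"unknown stem-loop format: {format}")
    return loops


def write_scan_report(rows: list[ScanRow], path: str | Path, *,
                      config: ScanConfig | None = None,
                      seed: int | None = None) -> pd.DataFrame:
    """Write the scan report TSV (sorted, fixed float precision) with a
    JSON sidecar holding the configuration, seed and package version.
    Re-running on identical inputs yields a byte-identical file."""
    from . import __version__

    frame = scan_to_frame(rows)
    path = Path(path)
    if len(frame):
        frame = frame.sort_values(["chrom", "pos", "mir_id"],
                                  key=lambda s: s.map(lambda v: str(v).zfill(2))
                                  if s.name == "chrom" else s)
        frame = frame.reset_index(drop=True)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
    sidecar = path.with_suffix(path.suffix + ".json")
    payload = {
        "version": __version__,
        "seed": seed,
        "config": dataclasses.asdict(config) if config is not None else None,
        "n_rows": int(len(frame)),
    }
    sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return frame


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON run-configuration file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    import yaml

    return yaml.safe_load(text)
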