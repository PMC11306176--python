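"""Offline gene-interval annotation of called regions.

Reads gene annotations from local GFF3 (feature type ``gene``) or BED
files, normalises coordinates to 1-based inclusive, and intersects them
with ROH islands or iHS candidate regions. Overlap is inclusive at the
boundaries: a single shared base pair (even an exact end-to-start touch)
counts, a rule stated explicitly because BED's 0-based half-open and
GFF3's 1-based inclusive conventions disagree at interval edges.
"""

from __future__ import annotations

import logging
import re
import warnings
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

GENE_COLUMNS = ["gene_id", "symbol", "chromosome", "start", "end", "description"]

_ATTR_RE = re.compile(r"(\w+)=([^;]*)")


def _norm_chrom(c: str) -> str:
    c = str(c).strip()
    return c[3:] if c.lower().startswith("chr") else c


def load_annotation(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Load gene records from a GFF3 or BED file.

    ``format`` defaults to the file extension. Malformed lines are skipped
    with a reported count; a file yielding zero genes raises.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower().lstrip(".")
        format = "gff3" if suffix in ("gff", "gff3") else suffix
    if format == "gff3":
        genes = _load_gff3(path)
    elif format == "bed":
        genes = _load_bed(path)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    if genes.empty:
        raise ValueError(f"{path}: no gene records loaded")
    bad = genes["start"] > genes["end"]
    if bad.any():
        raise ValueError(f"{path}: {int(bad.sum())} records with start > end")
    return genes.reset_index(drop=True)


def _load_gff3(path: Path) -> pd.DataFrame:
    rows, skipped = [], 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                skipped += 1
                continue
            if parts[2] != "gene":
                continue
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError:
                skipped += 1
                continue
            attrs = dict(_ATTR_RE.findall(parts[8]))
            gene_id = attrs.get("ID", attrs.get("gene_id", ""))
            gene_id = gene_id.removeprefix("gene:")
            rows.append(
                {
                    "gene_id": gene_id,
                    "symbol": attrs.get("Name", ""),
                    "chromosome": _norm_chrom(parts[0]),
                    "start": start,
                    "end": end,
                    "description": attrs.get("description", ""),
                }
            )
    if skipped:
        logger.warning("%s: skipped %d malformed lines", path, skipped)
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def _load_bed(path: Path) -> pd.DataFrame:
    rows, skipped = [], 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                skipped += 1
                continue
            try:
                start0, end0 = int(parts[1]), int(parts[2])
            except ValueError:
                skipped += 1
                continue
            name = parts[3] if len(parts) > 3 else f"{parts[0]}:{start0}-{end0}"
            rows.append(
                {
                    "gene_id": name,
                    "symbol": name,
                    "chromosome": _norm_chrom(parts[0]),
                    "start": start0 + 1,  # 0-based half-open -> 1-based inclusive
                    "end": end0,
                    "description": "",
                }
            )
    if skipped:
        logger.warning("%s: skipped %d malformed lines", path, skipped)
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def intersect(regions: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Genes overlapping each region (>= 1 shared bp, inclusive ends).

    ``regions`` needs ``chromosome, start_bp, end_bp`` columns. Genes with
    no symbol are reported by their id. Chromosome names present on one
    side only produce a warning listing the unmatched names.
    """
    if regions.empty:
        return pd.DataFrame(
            columns=["chromosome", "start_bp", "end_bp", "gene_id", "symbol", "description"]
        )
    reg_chroms = {_norm_chrom(c) for c in regions["chromosome"]}
    gene_chroms = set(genes["chromosome"].astype(str))
    unmatched = reg_chroms - gene_chroms
    if unmatched:
        warnings.warn(
            f"region chromosomes with no annotated genes: {sorted(unmatched)}"
        )
    rows = []
    for _, reg in regions.iterrows():
        chrom = _norm_chrom(reg["chromosome"])
        hits = genes[
            (genes["chromosome"].astype(str) == chrom)
            & (genes["start"] <= reg["end_bp"])
            & (genes["end"] >= reg["start_bp"])
        ]
        for _, gene in hits.iterrows():
            rows.append(
                {
                    "chromosome": reg["chromosome"],
                    "start_bp": reg["start_bp"],
                    "end_bp": reg["end_bp"],
                    "gene_id": gene["gene_id"],
                    "symbol": gene["symbol"] or gene["gene_id"],
                    "description": gene["description"],
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chromosome", "start_bp", "end_bp", "gene_id", "symbol", "description"],
    )
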