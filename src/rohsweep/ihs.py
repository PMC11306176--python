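"""Extended-haplotype selection scan: EHH, iHH, uniHS, iHS, p_iHS, regions.

For a core marker and one of its alleles, EHH at a target marker is the
probability that two random carrier haplotypes are identical at every
marker between the core and the target (inclusive):
``EHH = sum_h n_h (n_h - 1) / (n (n - 1))`` over the distinct extended
haplotypes ``h`` among the ``n`` carriers. iHH integrates the EHH curve
against physical position outward from the core (trapezoid rule, both
sides summed); integration on a side stops after the first marker where
EHH drops below ``ehh_cutoff`` (that last trapezoid is included), at the
chromosome end, or before any inter-marker gap above ``max_gap``.

The unstandardised score is ``uniHS = ln(iHH_A / iHH_D)``; standardising
within derived-allele-frequency bins of width 0.025 gives iHS, and
``p_iHS = -log10(2 Phi(-|iHS|))`` its two-sided Gaussian significance.
Sweeps on the derived allele push iHS negative; p_iHS is symmetric in
sign. Candidate regions are 1-Mb windows (consecutive starts 900 kb
apart by default) holding at least two markers with p_iHS above 4,
merged when they overlap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from rohsweep.types import HaplotypePanel

logger = logging.getLogger(__name__)

ANCESTRAL, DERIVED = 0, 1


@dataclass(frozen=True)
class ScanParams:
    """iHS scan parameters.

    ``step_mode="literal"`` reads "1-Mb windows overlapping the next by
    100 kb" literally (step = window_size - window_overlap = 900 kb);
    ``"rehh"`` uses the rehh calc_candidate_regions convention where the
    overlap argument is the step itself (step = 100 kb).
    """

    maf_min: float = 0.05
    ehh_cutoff: float = 0.05
    bin_width: float = 0.025
    max_gap: int = 1_000_000
    window_size: int = 1_000_000
    window_overlap: int = 100_000
    n_extremal: int = 2
    pihs_threshold: float = 4.0
    step_mode: str = "literal"

    def __post_init__(self) -> None:
        if not 0 < self.bin_width <= 0.5:
            raise ValueError("bin_width must be in (0, 0.5]")
        if self.window_overlap >= self.window_size:
            raise ValueError("window_overlap must be smaller than window_size")
        if self.step_mode not in ("literal", "rehh"):
            raise ValueError("step_mode must be 'literal' or 'rehh'")

    @property
    def window_step(self) -> int:
        if self.step_mode == "literal":
            return self.window_size - self.window_overlap
        return self.window_overlap


def _pair_homozygosity(labels: np.ndarray) -> float:
    """sum n_h(n_h-1) / (n(n-1)) over groups of identical labels."""
    n = labels.size
    if n < 2:
        raise ValueError("need at least two carrier haplotypes")
    _, counts = np.unique(labels, return_counts=True)
    return float((counts * (counts - 1)).sum()) / (n * (n - 1))


def ehh(h: HaplotypePanel, core: int, allele: int, target: int) -> float:
    """EHH of ``allele`` at marker index ``core`` out to marker ``target``.

    Core and target are indices into the panel's (sorted) map and must lie
    on the same chromosome. EHH at the core itself is 1 by definition.
    """
    chroms = h.map.chromosomes
    if chroms[core] != chroms[target]:
        raise ValueError("core and target on different chromosomes")
    carriers = h.haplotypes[:, core] == allele
    n = int(carriers.sum())
    if n < 2:
        raise ValueError("fewer than two carrier haplotypes")
    lo, hi = min(core, target), max(core, target)
    block = h.haplotypes[carriers, lo : hi + 1]
    # identity over the inclusive interval == identical rows
    _, labels = np.unique(block, axis=0, return_inverse=True)
    return _pair_homozygosity(labels)


def _ihh_one_side(
    hap: np.ndarray,
    pos: np.ndarray,
    core_local: int,
    carriers: np.ndarray,
    direction: int,
    cutoff: float,
    max_gap: int,
) -> float:
    """Trapezoid-integrated EHH marching outward in one direction."""
    n = int(carriers.sum())
    denom = n * (n - 1)
    labels = np.zeros(n, dtype=np.int64)  # all carriers identical at the core
    ehh_prev = 1.0
    pos_prev = pos[core_local]
    area = 0.0
    j = core_local
    limit = pos.size - 1 if direction > 0 else 0
    while j != limit:
        j_next = j + direction
        gap = abs(int(pos[j_next]) - int(pos[j]))
        if gap > max_gap:
            break  # truncate at the last marker before the gap
        alleles = hap[carriers, j_next]
        # refine the identity partition with the new marker: compacted
        # labels are < n, so label*2 + allele is a collision-free key
        _, labels = np.unique(labels * 2 + alleles, return_inverse=True)
        counts = np.bincount(labels)
        ehh_next = float((counts * (counts - 1)).sum()) / denom
        d = abs(int(pos[j_next]) - int(pos_prev))
        area += 0.5 * (ehh_prev + ehh_next) * d
        ehh_prev, pos_prev = ehh_next, pos[j_next]
        if ehh_next < cutoff:
            break  # final trapezoid already included
        j = j_next
    return area


def ihh(
    h: HaplotypePanel, core: int, allele: int, params: ScanParams | None = None
) -> float:
    """Integrated EHH (bp x EHH units) for one core allele, both sides summed."""
    p = params or ScanParams()
    chroms = h.map.chromosomes
    sl = h.map.chromosome_slices()[int(chroms[core])]
    hap = h.haplotypes[:, sl]
    pos = h.map.positions[sl]
    core_local = core - sl.start
    carriers = hap[:, core_local] == allele
    if int(carriers.sum()) < 2:
        raise ValueError("fewer than two carrier haplotypes")
    left = _ihh_one_side(hap, pos, core_local, carriers, -1, p.ehh_cutoff, p.max_gap)
    right = _ihh_one_side(hap, pos, core_local, carriers, +1, p.ehh_cutoff, p.max_gap)
    return left + right


def unihs(ihh_a: float, ihh_d: float) -> float:
    """Unstandardised score ln(iHH_ancestral / iHH_derived)."""
    if ihh_a <= 0 or ihh_d <= 0:
        raise ValueError("iHH values must be positive")
    return math.log(ihh_a / ihh_d)


def p_ihs(ihs: float | np.ndarray) -> float | np.ndarray:
    """Two-sided Gaussian significance on the -log10 scale."""
    return -np.log10(2.0 * stats.norm.sf(np.abs(ihs)))


def scan_unihs(h: HaplotypePanel, params: ScanParams | None = None) -> pd.DataFrame:
    """Per-marker iHH_A/iHH_D/uniHS for all markers passing the MAF filter.

    Markers with derived-allele frequency outside [maf_min, 1 - maf_min]
    or with a non-positive iHH on either allele are dropped (logged).
    """
    p = params or ScanParams()
    freqs = h.derived_frequencies()
    records = []
    n_dropped = 0
    for j in range(h.n_markers):
        f = freqs[j]
        if f < p.maf_min or f > 1 - p.maf_min:
            continue
        try:
            a = ihh(h, j, ANCESTRAL, p)
            d = ihh(h, j, DERIVED, p)
        except ValueError:
            n_dropped += 1
            continue
        if a <= 0 or d <= 0:
            n_dropped += 1
            continue
        records.append(
            {
                "marker_id": h.map.marker_ids.iloc[j],
                "chromosome": int(h.map.chromosomes[j]),
                "position": int(h.map.positions[j]),
                "derived_freq": float(f),
                "ihh_a": a,
                "ihh_d": d,
                "unihs": math.log(a / d),
            }
        )
    if n_dropped:
        logger.info("scan_unihs: %d markers dropped (degenerate iHH)", n_dropped)
    return pd.DataFrame(
        records,
        columns=[
            "marker_id", "chromosome", "position",
            "derived_freq", "ihh_a", "ihh_d", "unihs",
        ],
    )


def standardize(records: pd.DataFrame, bin_width: float = 0.025) -> pd.DataFrame:
    """Standardise uniHS within derived-frequency bins to mean 0, sd 1.

    Bins are left-closed, right-open over [0, 1] (frequency exactly 1
    falls in the last bin); bins with fewer than two members or zero
    spread are dropped with a log message. Adds ``ihs`` and ``p_ihs``.
    """
    n_bins = int(math.ceil(1.0 / bin_width))
    r = records.copy()
    # epsilon keeps frequencies that sit exactly on a bin edge (e.g. 0.30)
    # in their left-closed bin despite floating-point division
    b = np.minimum(
        np.floor(r["derived_freq"] / bin_width + 1e-9).astype(int), n_bins - 1
    )
    r["freq_bin"] = b
    out = []
    for _, grp in r.groupby("freq_bin"):
        if len(grp) < 2:
            logger.info("standardize: dropping %d markers in a singleton bin", len(grp))
            continue
        sd = grp["unihs"].std(ddof=1)
        if sd == 0:
            logger.info("standardize: dropping a zero-spread bin of %d markers", len(grp))
            continue
        g = grp.copy()
        g["ihs"] = (grp["unihs"] - grp["unihs"].mean()) / sd
        out.append(g)
    if not out:
        res = r.iloc[0:0].copy()
        res["ihs"] = pd.Series(dtype=float)
        res["p_ihs"] = pd.Series(dtype=float)
        return res
    res = pd.concat(out).sort_values(["chromosome", "position"]).reset_index(drop=True)
    res["p_ihs"] = p_ihs(res["ihs"].to_numpy())
    return res


def ihs_scan(h: HaplotypePanel, params: ScanParams | None = None) -> pd.DataFrame:
    """Full per-marker scan: MAF filter, iHH pair, uniHS, iHS, p_iHS."""
    p = params or ScanParams()
    return standardize(scan_unihs(h, p), p.bin_width)


def candidate_regions(
    records: pd.DataFrame, params: ScanParams | None = None
) -> pd.DataFrame:
    """Window the scan into candidate selection regions.

    Each chromosome is tiled with windows of ``window_size`` starting at
    position 1 with consecutive starts ``window_step`` apart; a window is
    significant when it holds at least ``n_extremal`` markers with
    ``p_ihs > pihs_threshold``. Overlapping significant windows merge into
    maximal regions reporting their extremal member markers.
    """
    p = params or ScanParams()
    regions = []
    for chrom, grp in records.groupby("chromosome"):
        pos = grp["position"].to_numpy()
        extremal = grp["p_ihs"].to_numpy() > p.pihs_threshold
        if extremal.sum() < p.n_extremal:
            continue
        last = int(pos.max())
        sig_windows = []
        start = 1
        while start <= last:
            end = start + p.window_size - 1
            inside = (pos >= start) & (pos <= end)
            if int((extremal & inside).sum()) >= p.n_extremal:
                sig_windows.append((start, end))
            start += p.window_step
        merged: list[list[int]] = []
        for s, e in sig_windows:
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            inside = (pos >= s) & (pos <= e)
            members = grp.loc[inside & extremal, "marker_id"]
            regions.append(
                {
                    "chromosome": int(chrom),
                    "start_bp": s,
                    "end_bp": e,
                    "n_extremal": int((inside & extremal).sum()),
                    "members": ",".join(members.astype(str)),
                }
            )
    return pd.DataFrame(
        regions,
        columns=["chromosome", "start_bp", "end_bp", "n_extremal", "members"],
    )


def write_scan_tsv(records: pd.DataFrame, path) -> None:
    """Plot-ready per-marker table (Manhattan-plot columns)."""
    out = pd.DataFrame(
        {
            "CHR": records["chromosome"],
            "SNP": records["marker_id"],
            "BP": records["position"],
            "derived_freq": records["derived_freq"],
            "iHH_A": records["ihh_a"],
            "iHH_D": records["ihh_d"],
            "uniHS": records["unihs"],
            "iHS": records.get("ihs"),
            "p_iHS": records.get("p_ihs"),
        }
    )
    out.to_csv(path, sep="\t", index=False)
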