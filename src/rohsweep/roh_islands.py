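"""ROH islands: per-marker ROH incidence and island calling.

An ROH island is a genomic region where an unusually high fraction of a
population's individuals carry a run of homozygosity — a footprint of
historical positive selection. Incidence at a marker is the percentage of
individuals with at least one ROH covering its position. Markers are
flagged when their incidence z-score (standardised over all autosomal
markers of the population jointly) exceeds the Gaussian 1 - tail quantile
(default tail 0.1%, i.e. Phi(z) > 0.999) *and* the incidence is at least
``min_incidence`` percent (default 20%, an additional restriction that
keeps the call from firing on populations where ROH are rare). Maximal
runs of consecutive flagged markers form islands.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from rohsweep.types import GenotypeMatrix

logger = logging.getLogger(__name__)


def roh_incidence(segments: pd.DataFrame, g: GenotypeMatrix) -> pd.DataFrame:
    """Percent of individuals whose ROH cover each marker.

    Returns a plot-ready table with columns
    ``CHR, SNP, BP, incidence`` in map order.
    """
    counts = np.zeros(g.map.n_markers, dtype=np.int64)
    slices = g.map.chromosome_slices()
    if not segments.empty:
        bad = set(segments["chromosome"]) - set(slices)
        if bad:
            raise ValueError(f"segments on chromosomes absent from the map: {sorted(bad)}")
        for (ind, chrom), seg in segments.groupby(["individual_id", "chromosome"]):
            sl = slices[chrom]
            pos = g.map.positions[sl]
            covered = np.zeros(pos.size, dtype=bool)
            for s, e in zip(seg["start_bp"], seg["end_bp"]):
                lo = np.searchsorted(pos, s, side="left")
                hi = np.searchsorted(pos, e, side="right")
                covered[lo:hi] = True
            counts[sl.start : sl.stop] += covered
    incidence = 100.0 * counts / g.n_individuals
    return pd.DataFrame(
        {
            "CHR": g.map.chromosomes,
            "SNP": g.map.marker_ids.to_numpy(),
            "BP": g.map.positions,
            "incidence": incidence,
        }
    )


def flag_markers(
    incidence: np.ndarray,
    min_incidence: float = 20.0,
    tail: float = 0.001,
    mode: str = "gaussian",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Significance call per marker; returns (z, Phi(z), flagged).

    ``mode="gaussian"`` thresholds Phi(z) > 1 - tail (primary);
    ``mode="empirical"`` flags the top ``tail`` fraction by rank — the two
    differ on skewed incidence distributions.
    """
    inc = np.asarray(incidence, dtype=float)
    sd = inc.std(ddof=1) if inc.size > 1 else 0.0
    if sd == 0:
        logger.warning("incidence has zero variance; no islands can be called")
        z = np.zeros_like(inc)
        return z, stats.norm.cdf(z), np.zeros(inc.size, dtype=bool)
    z = (inc - inc.mean()) / sd
    phi = stats.norm.cdf(z)
    if mode == "gaussian":
        sig = phi > 1.0 - tail
    elif mode == "empirical":
        cutoff = np.quantile(inc, 1.0 - tail)
        sig = inc > cutoff
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return z, phi, sig & (inc >= min_incidence)


def call_islands(
    incidence_table: pd.DataFrame,
    min_incidence: float = 20.0,
    tail: float = 0.001,
    mode: str = "gaussian",
    population: str = "",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call ROH islands from a per-marker incidence table.

    Returns ``(markers, islands)``: the input table augmented with ``z``,
    ``phi`` and ``significant`` columns, and one row per island spanning
    its first to last member SNP.
    """
    if len(incidence_table) < 2:
        raise ValueError("need at least two markers")
    t = incidence_table.reset_index(drop=True).copy()
    z, phi, sig = flag_markers(t["incidence"].to_numpy(), min_incidence, tail, mode)
    t["z"] = z
    t["phi"] = phi
    t["significant"] = sig
    islands = []
    for chrom, grp in t.groupby("CHR", sort=False):
        flags = grp["significant"].to_numpy()
        if not flags.any():
            continue
        idx = grp.index.to_numpy()
        edges = np.flatnonzero(np.diff(flags.astype(np.int8)))
        starts = [0] + list(edges + 1)
        ends = list(edges) + [flags.size - 1]
        for s, e in zip(starts, ends):
            if not flags[s]:
                continue
            member = grp.iloc[s : e + 1]
            islands.append(
                {
                    "chromosome": chrom,
                    "start_bp": int(member["BP"].iloc[0]),
                    "end_bp": int(member["BP"].iloc[-1]),
                    "n_snp": len(member),
                    "peak_incidence": float(member["incidence"].max()),
                    "members": ",".join(member["SNP"].astype(str)),
                    "population": population,
                }
            )
    island_df = pd.DataFrame(
        islands,
        columns=[
            "chromosome", "start_bp", "end_bp", "n_snp",
            "peak_incidence", "members", "population",
        ],
    )
    return t, island_df


def write_islands_bed(islands: pd.DataFrame, path) -> None:
    """Islands as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for _, row in islands.iterrows():
            fh.write(f"{row['chromosome']}\t{row['start_bp'] - 1}\t{row['end_bp']}\n")
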