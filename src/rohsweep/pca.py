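"""LD pruning and principal component analysis of SNP genotypes.

Pruning slides a ``window_snp``-marker window in ``step_snp`` steps and
greedily removes one member of every within-window pair whose squared
Pearson correlation of dosages exceeds ``r2_max`` (pairwise-complete on
missing calls), leaving a quasi-independent marker set. PCA mean-imputes
missing dosages, centres at ``2p`` and standardises by ``sqrt(2p(1-p))``
— the genomic-relationship-matrix convention — then eigendecomposes the
sample-by-sample covariance; explained variance is each eigenvalue as a
percentage of the trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from rohsweep.types import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


def _window_r2(x: np.ndarray) -> np.ndarray:
    """Pairwise r^2 of dosage columns, pairwise-complete over missing."""
    df = pd.DataFrame(np.where(x == MISSING, np.nan, x.astype(float)))
    r = df.corr().to_numpy()
    return np.nan_to_num(r) ** 2


def ld_prune(
    g: GenotypeMatrix,
    window_snp: int = 50,
    step_snp: int = 10,
    r2_max: float = 0.1,
) -> np.ndarray:
    """Indices of markers retained after windowed r^2 pruning.

    Within each window the pair with the highest r^2 above the threshold
    is resolved by removing the member with the smaller minor-allele
    frequency (ties: the later map position), repeating until no pair
    exceeds the threshold; the window then slides by ``step_snp``.
    Deterministic given the tie-break rule.
    """
    if window_snp < 2 or step_snp < 1:
        raise ValueError("window_snp must be >= 2 and step_snp >= 1")
    freqs = g.allele_frequencies()
    maf = np.minimum(freqs, 1 - freqs)
    keep = np.ones(g.n_markers, dtype=bool)
    for chrom, sl in g.map.chromosome_slices().items():
        idx_chrom = np.arange(sl.start, sl.stop)
        start = 0
        while start < idx_chrom.size:
            win = idx_chrom[start : start + window_snp]
            live = win[keep[win]]
            while live.size >= 2:
                r2 = _window_r2(g.calls[:, live])
                np.fill_diagonal(r2, 0.0)
                a, b = np.unravel_index(np.argmax(r2), r2.shape)
                if r2[a, b] <= r2_max:
                    break
                ia, ib = live[a], live[b]
                if maf[ia] < maf[ib]:
                    drop = ia
                elif maf[ib] < maf[ia]:
                    drop = ib
                else:
                    drop = max(ia, ib)  # tie: later map position
                keep[drop] = False
                live = win[keep[win]]
            if start + window_snp >= idx_chrom.size:
                break
            start += step_snp
    return np.flatnonzero(keep)


@dataclass
class PCAResult:
    """Sample scores, explained-variance percentages and markers used."""

    scores: pd.DataFrame  # individuals x components, PLINK .eigenvec-like
    explained_pct: np.ndarray  # per component, non-increasing, sums to <= 100
    eigenvalues: np.ndarray
    n_markers_used: int

    def write_tsv(self, prefix) -> None:
        self.scores.to_csv(f"{prefix}.eigenvec.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"eigenvalue": self.eigenvalues, "explained_pct": self.explained_pct}
        ).to_csv(f"{prefix}.eigenval.tsv", sep="\t", index=False)


def pca(g: GenotypeMatrix, n_components: int = 10) -> PCAResult:
    """Principal components of the standardised dosage matrix.

    Monomorphic (or all-missing) markers are dropped with a log message;
    component sign is unconstrained.
    """
    if g.n_individuals < 2 or g.n_markers < 2:
        raise ValueError("need at least two samples and two markers")
    p = g.allele_frequencies()
    keep = np.isfinite(p) & (p > 0) & (p < 1)
    dropped = g.n_markers - int(keep.sum())
    if dropped:
        logger.info("pca: dropped %d zero-variance markers", dropped)
    if keep.sum() < 2:
        raise ValueError("fewer than two polymorphic markers")
    p = p[keep]
    x = g.calls[:, keep].astype(float)
    x[x == MISSING] = np.nan
    mean = 2 * p
    x = np.where(np.isnan(x), mean, x)  # mean imputation
    z = (x - mean) / np.sqrt(2 * p * (1 - p))
    m = z.shape[1]
    grm = z @ z.T / m
    eigval, eigvec = np.linalg.eigh(grm)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0, None)
    eigvec = eigvec[:, order]
    k = min(n_components, len(eigval))
    total = eigval.sum()
    explained = 100.0 * eigval / total if total > 0 else np.zeros_like(eigval)
    scores = pd.DataFrame(
        eigvec[:, :k], columns=[f"PC{i + 1}" for i in range(k)]
    )
    scores.insert(0, "IID", g.samples["individual_id"].to_numpy())
    scores.insert(0, "FID", g.samples["population"].to_numpy())
    return PCAResult(
        scores=scores,
        explained_pct=explained[:k],
        eigenvalues=eigval[:k],
        n_markers_used=m,
    )
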