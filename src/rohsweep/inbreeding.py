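"""Genomic inbreeding coefficients: F_ROH, F_GRM, F_HOM, F_UNI.

F_ROH is the fraction of the mapped autosomal genome lying in runs of
homozygosity. The three marker-based estimators are the classic GCTA/PLINK
``--ibc`` trio computed from alt-allele dosage ``x`` and sample allele
frequency ``p``:

* F_GRM  — diagonal of the variance-standardised genomic relationship
  matrix minus one: ``mean[(x - 2p)^2 / (2p(1-p))] - 1``;
* F_HOM  — excess of observed over expected homozygotes:
  ``(O_hom - E_hom) / (m - E_hom)`` with ``E_hom = sum(1 - 2p(1-p))``;
* F_UNI  — correlation between uniting gametes:
  ``mean[(x^2 - (1+2p)x + 2p^2) / (2p(1-p))]``.

Frequencies are sample frequencies of the analysis population (computed
after QC); monomorphic markers are excluded from the three marker-based
estimators (never from ROH detection), and an individual's missing calls
are skipped with its marker count adjusted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from rohsweep.types import MISSING, GenotypeMatrix
from rohsweep.roh_detection import LENGTH_CLASS_EDGES_MB, LENGTH_CLASS_LABELS

METRIC_COLUMNS = ["f_roh", "f_grm", "f_hom", "f_uni"]


def f_roh(
    segments: pd.DataFrame,
    l_auto: int,
    individuals: list[str],
) -> pd.DataFrame:
    """Per-individual F_ROH, overall and per length class.

    ``l_auto`` is the autosomal length covered by SNPs (sum over
    chromosomes of the mapped extent, or a user-supplied table).
    Individuals without segments get zeros.
    """
    if l_auto <= 0:
        raise ValueError("l_auto must be positive")
    out = pd.DataFrame(
        0.0,
        index=pd.Index(individuals, name="individual_id"),
        columns=["f_roh", *(f"f_roh_{c}" for c in LENGTH_CLASS_LABELS)],
    )
    if segments.empty:
        return out
    unknown = set(segments["individual_id"]) - set(individuals)
    if unknown:
        raise ValueError(f"segments for unknown individuals {sorted(unknown)}")
    cls = pd.cut(
        segments["length_mb"],
        bins=LENGTH_CLASS_EDGES_MB,
        labels=LENGTH_CLASS_LABELS,
        right=False,
        include_lowest=True,
    )
    total = segments.groupby("individual_id")["length_bp"].sum() / float(l_auto)
    out.loc[total.index, "f_roh"] = total
    per_class = (
        segments["length_bp"]
        .groupby([segments["individual_id"], cls], observed=False)
        .sum()
        .unstack(fill_value=0)
        / float(l_auto)
    )
    for c in LENGTH_CLASS_LABELS:
        if c in per_class.columns:
            out.loc[per_class.index, f"f_roh_{c}"] = per_class[c]
    return out


def _polymorphic(freqs: np.ndarray) -> np.ndarray:
    return np.isfinite(freqs) & (freqs > 0) & (freqs < 1)


def _prepare(g: GenotypeMatrix, freqs: np.ndarray | None):
    p = g.allele_frequencies() if freqs is None else np.asarray(freqs, dtype=float)
    keep = _polymorphic(p)
    if not keep.any():
        raise ValueError("all markers monomorphic; marker-based metrics undefined")
    x = g.calls[:, keep].astype(float)
    x[x == MISSING] = np.nan
    return x, p[keep]


def f_grm(g: GenotypeMatrix, freqs: np.ndarray | None = None) -> pd.Series:
    """Variance-standardised relationship diagonal minus one (Fhat1)."""
    x, p = _prepare(g, freqs)
    terms = (x - 2 * p) ** 2 / (2 * p * (1 - p))
    vals = np.nanmean(terms, axis=1) - 1.0
    return pd.Series(vals, index=g.samples["individual_id"].to_numpy(), name="f_grm")


def f_hom(g: GenotypeMatrix, freqs: np.ndarray | None = None) -> pd.Series:
    """Excess-homozygosity estimator (Fhat2)."""
    x, p = _prepare(g, freqs)
    obs = np.isfinite(x)
    hom = obs & (x != 1)
    e_hom_marker = 1.0 - 2 * p * (1 - p)
    e_hom = obs.astype(float) @ e_hom_marker
    m = obs.sum(axis=1).astype(float)
    o_hom = hom.sum(axis=1).astype(float)
    denom = m - e_hom
    if np.any(denom <= 0):
        raise ValueError("degenerate expected homozygosity (requires p in {0,1})")
    vals = (o_hom - e_hom) / denom
    return pd.Series(vals, index=g.samples["individual_id"].to_numpy(), name="f_hom")


def f_uni(g: GenotypeMatrix, freqs: np.ndarray | None = None) -> pd.Series:
    """Uniting-gametes correlation estimator (Fhat3)."""
    x, p = _prepare(g, freqs)
    terms = (x**2 - (1 + 2 * p) * x + 2 * p**2) / (2 * p * (1 - p))
    vals = np.nanmean(terms, axis=1)
    return pd.Series(vals, index=g.samples["individual_id"].to_numpy(), name="f_uni")


def inbreeding_profiles(
    g: GenotypeMatrix,
    segments: pd.DataFrame,
    l_auto: int | None = None,
    freqs: np.ndarray | None = None,
) -> pd.DataFrame:
    """All four coefficients per individual in one table.

    ``l_auto`` defaults to the mapped autosomal extent of the panel's map.
    """
    if l_auto is None:
        l_auto = sum(g.map.chromosome_lengths().values())
    prof = f_roh(segments, l_auto, list(g.samples["individual_id"]))
    prof["f_grm"] = f_grm(g, freqs)
    prof["f_hom"] = f_hom(g, freqs)
    prof["f_uni"] = f_uni(g, freqs)
    return prof


def metric_correlations(
    profiles: pd.DataFrame, columns: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations of the metric columns, with p-values.

    Returns (r, p) symmetric matrices with unit diagonal; a zero-variance
    column yields NaN entries. Two-sided p-values come from the usual
    t-transform of r with n-2 degrees of freedom.
    """
    cols = columns or [c for c in METRIC_COLUMNS if c in profiles.columns]
    data = profiles[cols].to_numpy(dtype=float)
    n = data.shape[0]
    if n < 3:
        raise ValueError("need at least three individuals for correlations")
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            xa, xb = data[:, a], data[:, b]
            if np.std(xa) == 0 or np.std(xb) == 0:
                r[a, b] = r[b, a] = np.nan
                p[a, b] = p[b, a] = np.nan
                continue
            res = stats.pearsonr(xa, xb)
            r[a, b] = r[b, a] = res.statistic
            p[a, b] = p[b, a] = res.pvalue
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


def significance_stars(p: float) -> str:
    """Annotation scheme for correlation tables: *** / ** / * at 0.001/0.01/0.05."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def write_correlation_tsv(r: pd.DataFrame, p: pd.DataFrame, path) -> None:
    annotated = r.round(3).astype(str) + p.map(significance_stars)
    annotated.to_csv(path, sep="\t")
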