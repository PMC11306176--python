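"""Core in-memory containers: marker map, genotype matrix, haplotype panel.

Conventions used throughout the package:

* genotypes are alt-allele (``allele_b``) dosages in ``{0, 1, 2}`` with
  :data:`MISSING` (``-1``) as the missing sentinel, stored as ``int8``;
* positions are 1-based inclusive base pairs (PLINK convention);
* haplotypes are binary, ``0`` = ancestral, ``1`` = derived, never missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Missing-genotype sentinel (internal; "0 0" in .ped, two-bit 01 in .bed).
MISSING: int = -1

_MAP_COLUMNS = ["chromosome", "position", "marker_id", "allele_a", "allele_b"]


@dataclass
class MarkerMap:
    """Per-marker chromosome, physical position and allele labels.

    Markers are sorted by (chromosome, position) on construction; duplicate
    positions are allowed, duplicate marker ids are not. Chromosomes are
    positive integers (1..29 for cattle autosomes, but any positive integer
    is accepted).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing_cols = set(_MAP_COLUMNS) - set(self.table.columns)
        if missing_cols:
            raise ValueError(f"marker map lacks columns {sorted(missing_cols)}")
        t = self.table.reset_index(drop=True).copy()
        t["chromosome"] = t["chromosome"].astype(int)
        t["position"] = t["position"].astype(np.int64)
        if (t["chromosome"] <= 0).any():
            raise ValueError("chromosome labels must be positive integers")
        if t["marker_id"].duplicated().any():
            dup = t.loc[t["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise ValueError(f"duplicate marker id {dup!r}")
        order = np.lexsort((t["position"].to_numpy(), t["chromosome"].to_numpy()))
        if not np.array_equal(order, np.arange(len(t))):
            warnings.warn("marker map unsorted; sorting by (chromosome, position)")
        self.table = t.iloc[order].reset_index(drop=True)
        self._sort_order = order

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> np.ndarray:
        return self.table["chromosome"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.table["position"].to_numpy()

    @property
    def marker_ids(self) -> pd.Series:
        return self.table["marker_id"]

    def chromosome_slices(self) -> dict[int, slice]:
        """Contiguous index slice per chromosome (map is sorted)."""
        chroms = self.chromosomes
        out: dict[int, slice] = {}
        if len(chroms) == 0:
            return out
        bounds = np.flatnonzero(np.diff(chroms)) + 1
        starts = np.concatenate([[0], bounds])
        ends = np.concatenate([bounds, [len(chroms)]])
        for s, e in zip(starts, ends):
            out[int(chroms[s])] = slice(int(s), int(e))
        return out

    def chromosome_lengths(self) -> dict[int, int]:
        """Mapped extent per chromosome: position of the last SNP."""
        return {
            c: int(self.positions[sl].max()) for c, sl in self.chromosome_slices().items()
        }

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.table.iloc[np.asarray(idx)].reset_index(drop=True))


def _roster(samples: pd.DataFrame) -> pd.DataFrame:
    if not {"individual_id", "population"} <= set(samples.columns):
        raise ValueError("sample roster needs individual_id and population columns")
    return samples.reset_index(drop=True)


@dataclass
class GenotypeMatrix:
    """N individuals x M markers of alt-allele dosage bound to a marker map."""

    samples: pd.DataFrame
    calls: np.ndarray
    map: MarkerMap

    def __post_init__(self) -> None:
        self.samples = _roster(self.samples)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (individuals x markers)")
        n, m = self.calls.shape
        if n != len(self.samples):
            raise ValueError(f"{n} call rows but {len(self.samples)} samples")
        if m != self.map.n_markers:
            raise ValueError(f"{m} call columns but {self.map.n_markers} mapped markers")
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("calls must be 0/1/2 or the missing sentinel")

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def allele_frequencies(self) -> np.ndarray:
        """Sample frequency of allele_b per marker, missing calls skipped.

        Markers with all calls missing get frequency nan.
        """
        calls = self.calls.astype(float)
        calls[self.missing_mask()] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(calls, axis=0) / 2.0

    def subset_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(self.samples, self.calls[:, idx], self.map.subset(idx))

    def subset_individuals(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.samples.iloc[idx].reset_index(drop=True), self.calls[idx], self.map
        )


@dataclass
class HaplotypePanel:
    """2N x M phased binary haplotypes (0 ancestral, 1 derived), no missing.

    Rows ``2i`` and ``2i+1`` are the two haplotypes of individual ``i``.
    ``ancestral_source`` records, per marker, how the ancestral allele was
    assigned: ``"coded"`` (taken from file orientation), ``"user"`` (from a
    user table) or ``"major"`` (major-allele fallback).
    """

    haplotypes: np.ndarray
    map: MarkerMap
    samples: pd.DataFrame
    ancestral_source: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.samples = _roster(self.samples)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be 2-D")
        h, m = self.haplotypes.shape
        if h % 2 != 0:
            raise ValueError("odd haplotype count")
        if h != 2 * len(self.samples):
            raise ValueError(f"{h} haplotypes but {len(self.samples)} individuals")
        if m != self.map.n_markers:
            raise ValueError("haplotype/map marker mismatch")
        if not np.isin(self.haplotypes, [0, 1]).all():
            raise ValueError("haplotype alleles must be 0 or 1")
        if self.ancestral_source is None:
            self.ancestral_source = np.full(m, "coded", dtype=object)
        else:
            self.ancestral_source = np.asarray(self.ancestral_source, dtype=object)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]

    def derived_frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    def to_genotypes(self) -> GenotypeMatrix:
        """Collapse phased haplotypes to dosage genotypes (no missingness)."""
        dos = self.haplotypes[0::2].astype(np.int8) + self.haplotypes[1::2]
        return GenotypeMatrix(self.samples, dos, self.map)
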