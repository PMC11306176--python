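"""Synthetic genotype/haplotype panels with planted ROH, sweeps and structure.

The generator emulates a medium-density SNP array (about one marker per
51 kb, the density of a bovine 50K chip) on autosomes of configurable
length. The neutral background is linkage equilibrium: every marker's
alleles are drawn independently at a frequency sampled from a uniform MAF
distribution. Planted homozygous tracts and planted sweeps are therefore
the *only* long-range haplotype structure, which makes recovery tests
sharp; real array data carries background LD that this baseline does not
model (see docs/methods.md).

Ground truth for every planted feature is recorded in a
:class:`TruthTable` so downstream detectors can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rohsweep.types import MISSING, GenotypeMatrix, HaplotypePanel, MarkerMap

_ROH_COLUMNS = ["individual_id", "chromosome", "start_bp", "end_bp", "n_snp"]
_SWEEP_COLUMNS = [
    "chromosome",
    "core_marker_id",
    "core_position",
    "derived_freq",
    "shared_length_bp",
    "n_carriers",
]


@dataclass
class TruthTable:
    """Ground truth of all planted features, keyed by the generator seed."""

    seed: int
    chromosome_lengths: dict[int, int]
    roh: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=_ROH_COLUMNS)
    )
    sweeps: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=_SWEEP_COLUMNS)
    )

    def planted_f_roh(self, l_auto: int | None = None) -> pd.Series:
        """Planted ROH fraction per individual: summed tract length / genome.

        ``l_auto`` defaults to the summed simulated chromosome lengths.
        Tract lengths use the marker-snapped inclusive coordinates recorded
        at planting time.
        """
        if l_auto is None:
            l_auto = sum(self.chromosome_lengths.values())
        if self.roh.empty:
            return pd.Series(dtype=float)
        lengths = self.roh["end_bp"] - self.roh["start_bp"] + 1
        return lengths.groupby(self.roh["individual_id"]).sum() / float(l_auto)

    def write_tsv(self, prefix) -> None:
        self.roh.to_csv(f"{prefix}.roh_truth.tsv", sep="\t", index=False)
        self.sweeps.to_csv(f"{prefix}.sweep_truth.tsv", sep="\t", index=False)
        meta = pd.DataFrame(
            {
                "chromosome": list(self.chromosome_lengths),
                "length_bp": list(self.chromosome_lengths.values()),
                "seed": self.seed,
            }
        )
        meta.to_csv(f"{prefix}.panel_truth.tsv", sep="\t", index=False)


@dataclass
class SyntheticPanel:
    """A simulated dataset: genotypes + the phased haplotypes they came from."""

    genotypes: GenotypeMatrix
    haplotypes: HaplotypePanel
    truth: TruthTable

    def resync_genotypes(self, markers: np.ndarray) -> None:
        """Recompute dosages from haplotypes at ``markers``, keeping missingness."""
        miss = self.genotypes.calls[:, markers] == MISSING
        h = self.haplotypes.haplotypes
        dos = (h[0::2][:, markers].astype(np.int8) + h[1::2][:, markers]).astype(np.int8)
        dos[miss] = MISSING
        self.genotypes.calls[:, markers] = dos


def simulate_panel(
    n_ind: int,
    chromosomes: list[tuple[int, int]] = ((1, 25_000_000),),
    snp_spacing: int = 51_000,
    maf_dist: tuple[float, float] = (0.05, 0.5),
    missing_rate: float = 0.0,
    seed: int = 0,
    population: str = "SIM",
) -> SyntheticPanel:
    """Simulate a neutral linkage-equilibrium panel.

    Marker positions are cumulative exponential gaps with mean
    ``snp_spacing`` (so marker count per chromosome is about
    length/spacing); each marker's allele frequency is drawn from
    ``uniform(*maf_dist)`` and haplotype alleles are i.i.d. Bernoulli
    draws at that frequency. Genotypes are the sums of the two haplotypes,
    then masked missing at ``missing_rate`` (haplotypes stay complete, as
    phased input is assumed complete downstream).
    """
    lo, hi = maf_dist
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_dist bounds must satisfy 0 < lo <= hi <= 0.5")
    if n_ind <= 0 or snp_spacing <= 0:
        raise ValueError("n_ind and snp_spacing must be positive")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, length in chromosomes:
        n_draw = max(int(2 * length / snp_spacing) + 16, 16)
        gaps = rng.exponential(snp_spacing, size=n_draw)
        pos = np.unique(np.cumsum(gaps).astype(np.int64) + 1)
        pos = pos[pos <= length]
        if pos.size == 0:
            raise ValueError(f"zero markers on chromosome {chrom}")
        rows.append(
            pd.DataFrame(
                {
                    "chromosome": chrom,
                    "position": pos,
                    "marker_id": [f"chr{chrom}_snp{i}" for i in range(pos.size)],
                    "allele_a": "A",
                    "allele_b": "G",
                }
            )
        )
    mm = MarkerMap(pd.concat(rows, ignore_index=True))
    m = mm.n_markers
    # the drawn value is a minor-allele frequency; the derived allele is the
    # minor or the major one with equal probability, as in oriented real
    # data, so derived frequencies populate both halves of [0, 1]
    maf = rng.uniform(lo, hi, size=m)
    freqs = np.where(rng.random(m) < 0.5, maf, 1.0 - maf)
    hap = (rng.random((2 * n_ind, m)) < freqs).astype(np.uint8)
    samples = pd.DataFrame(
        {
            "individual_id": [f"ind{i}" for i in range(n_ind)],
            "population": population,
        }
    )
    hp = HaplotypePanel(hap, mm, samples)
    gm = hp.to_genotypes()
    if missing_rate > 0:
        mask = rng.random(gm.calls.shape) < missing_rate
        gm.calls[mask] = MISSING
    truth = TruthTable(seed=seed, chromosome_lengths={c: l for c, l in chromosomes})
    return SyntheticPanel(gm, hp, truth)


def plant_roh(
    panel: SyntheticPanel,
    individual: str,
    chromosome: int,
    start: int,
    length: int,
) -> SyntheticPanel:
    """Overwrite one individual's two haplotypes with a shared tract.

    Every marker in ``[start, start + length)`` becomes homozygous for that
    individual (haplotype 2 copies haplotype 1). The truth table records the
    tract snapped to the covered markers (positions of the first and last
    covered SNP, inclusive), so boundary recovery is well defined.
    """
    ids = panel.genotypes.samples["individual_id"]
    matches = np.flatnonzero(ids == individual)
    if matches.size != 1:
        raise KeyError(f"unknown individual {individual!r}")
    i = int(matches[0])
    mm = panel.genotypes.map
    if chromosome not in panel.truth.chromosome_lengths:
        raise KeyError(f"unknown chromosome {chromosome}")
    clen = panel.truth.chromosome_lengths[chromosome]
    if start < 1 or start + length - 1 > clen:
        raise ValueError("planted tract outside chromosome bounds")
    on_chrom = mm.chromosomes == chromosome
    cover = on_chrom & (mm.positions >= start) & (mm.positions < start + length)
    idx = np.flatnonzero(cover)
    if idx.size == 0:
        raise ValueError("planted tract covers no markers")
    h = panel.haplotypes.haplotypes
    h[2 * i + 1, idx] = h[2 * i, idx]
    panel.resync_genotypes(idx)
    rec = pd.DataFrame(
        [
            {
                "individual_id": individual,
                "chromosome": chromosome,
                "start_bp": int(mm.positions[idx[0]]),
                "end_bp": int(mm.positions[idx[-1]]),
                "n_snp": int(idx.size),
            }
        ]
    )
    panel.truth.roh = (
        rec if panel.truth.roh.empty
        else pd.concat([panel.truth.roh, rec], ignore_index=True)
    )
    return panel


def plant_sweep(
    panel: SyntheticPanel,
    chromosome: int,
    core_position: int,
    derived_freq: float,
    shared_length: int,
) -> SyntheticPanel:
    """Plant a hard selective sweep: one extended haplotype at high frequency.

    A fraction ``derived_freq`` of haplotypes (rounded to a count) is chosen
    at random, given the derived allele at the marker nearest
    ``core_position``, and overwritten with one identical allele sequence
    over +-``shared_length`` around the core; EHH among carriers is
    therefore exactly 1 across that span. Non-carriers keep the neutral
    background and the ancestral core allele.
    """
    if not 0 < derived_freq < 1:
        raise ValueError("derived_freq must be in (0, 1)")
    mm = panel.genotypes.map
    on_chrom = np.flatnonzero(mm.chromosomes == chromosome)
    if on_chrom.size == 0:
        raise KeyError(f"no markers on chromosome {chromosome}")
    core = int(on_chrom[np.argmin(np.abs(mm.positions[on_chrom] - core_position))])
    core_pos = int(mm.positions[core])
    n_hap = panel.haplotypes.n_haplotypes
    n_carriers = int(round(derived_freq * n_hap))
    if n_carriers < 2:
        raise ValueError("derived_freq yields fewer than two carrier haplotypes")
    rng = np.random.default_rng([panel.truth.seed & 0x7FFFFFFF, 0x5EE9, core])
    carriers = rng.choice(n_hap, size=n_carriers, replace=False)
    span = on_chrom[
        (mm.positions[on_chrom] >= core_pos - shared_length)
        & (mm.positions[on_chrom] <= core_pos + shared_length)
    ]
    h = panel.haplotypes.haplotypes
    template = h[carriers[0], span].copy()
    h[np.ix_(carriers, span)] = template
    h[:, core] = 0
    h[carriers, core] = 1
    panel.resync_genotypes(span)
    rec = pd.DataFrame(
        [
            {
                "chromosome": chromosome,
                "core_marker_id": mm.marker_ids.iloc[core],
                "core_position": core_pos,
                "derived_freq": derived_freq,
                "shared_length_bp": shared_length,
                "n_carriers": n_carriers,
            }
        ]
    )
    panel.truth.sweeps = (
        rec if panel.truth.sweeps.empty
        else pd.concat([panel.truth.sweeps, rec], ignore_index=True)
    )
    return panel


def simulate_structured_panels(
    n_pops: int,
    n_ind_per_pop: int,
    divergence: float,
    chromosomes: list[tuple[int, int]] = ((1, 25_000_000),),
    snp_spacing: int = 51_000,
    ancestral_freq_dist: tuple[float, float] = (0.1, 0.9),
    seed: int = 0,
) -> tuple[GenotypeMatrix, TruthTable]:
    """Simulate differentiated populations under a Balding-Nichols model.

    Each population's allele frequency at a marker is a Beta draw around a
    shared ancestral frequency ``p`` with parameters
    ``p(1-F)/F, (1-p)(1-F)/F`` where ``F`` is the drift/differentiation
    parameter (``divergence``); ``F = 0`` makes populations exchangeable.
    Genotypes are Hardy-Weinberg binomial draws within populations.
    """
    if n_pops < 2:
        raise ValueError("need at least two populations")
    if divergence < 0:
        raise ValueError("divergence must be non-negative")
    rng = np.random.default_rng(seed)
    neutral = simulate_panel(
        n_ind=1, chromosomes=chromosomes, snp_spacing=snp_spacing, seed=seed
    )
    mm = neutral.genotypes.map
    m = mm.n_markers
    lo, hi = ancestral_freq_dist
    p_anc = rng.uniform(lo, hi, size=m)
    calls, sample_rows = [], []
    for k in range(n_pops):
        if divergence > 0:
            a = p_anc * (1 - divergence) / divergence
            b = (1 - p_anc) * (1 - divergence) / divergence
            p_pop = rng.beta(a, b)
        else:
            p_pop = p_anc
        calls.append(
            rng.binomial(2, p_pop, size=(n_ind_per_pop, m)).astype(np.int8)
        )
        sample_rows += [
            {"individual_id": f"pop{k}_ind{i}", "population": f"pop{k}"}
            for i in range(n_ind_per_pop)
        ]
    gm = GenotypeMatrix(pd.DataFrame(sample_rows), np.vstack(calls), mm)
    truth = TruthTable(seed=seed, chromosome_lengths={c: l for c, l in chromosomes})
    return gm, truth
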