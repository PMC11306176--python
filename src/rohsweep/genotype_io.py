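"""Readers/writers for PLINK and Oxford formats, QC, panel merging.

PLINK text (.ped/.map) and binary (.bed/.bim/.fam, v1 SNP-major) genotype
sets round-trip bit-exactly through :class:`~rohsweep.types.GenotypeMatrix`;
phased haplotypes use the Oxford .haps/.sample pair. Quality control follows
the usual SNP-array recipe for ROH studies: drop non-autosomal markers, then
individuals by call rate, then SNPs by call rate — no MAF, HWE or LD
filtering at this stage, which would bias downstream homozygosity scans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from rohsweep.types import MISSING, GenotypeMatrix, HaplotypePanel, MarkerMap

logger = logging.getLogger(__name__)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# two-bit PLINK codes -> dosage: 00 hom A1, 01 missing, 10 het, 11 hom A2
_CODE_TO_DOSAGE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_DOSAGE_TO_CODE = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}

# per-byte lookup: byte value -> 4 dosages (individuals packed LSB-first)
_BYTE_LUT = np.empty((256, 4), dtype=np.int8)
for _b in range(256):
    for _j in range(4):
        _BYTE_LUT[_b, _j] = _CODE_TO_DOSAGE[(_b >> (2 * _j)) & 0b11]


# ---------------------------------------------------------------------------
# PLINK genotypes


def _read_map_file(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if df.shape[1] < 4:
        raise ValueError(f"{path}: expected 4 columns (chrom, id, cM, bp)")
    return pd.DataFrame(
        {
            "chromosome": df[0].astype(int),
            "position": df[3].astype(np.int64),
            "marker_id": df[1],
        }
    )


def _infer_alleles(col_a: np.ndarray, col_b: np.ndarray) -> tuple[str, str]:
    """Allele labels for one marker from its two .ped allele columns.

    The lexicographically smaller observed allele becomes ``allele_a``;
    monomorphic markers get the PLINK-style unknown label ``"0"`` as
    ``allele_a`` so that dosage (count of ``allele_b``) is well defined.
    """
    seen = sorted(set(col_a) | set(col_b) - {"0"})
    seen = [a for a in seen if a != "0"]
    if len(seen) > 2:
        raise ValueError(f"more than two alleles observed: {seen}")
    if len(seen) == 0:
        return "0", "0"
    if len(seen) == 1:
        return "0", seen[0]
    return seen[0], seen[1]


def read_plink(prefix: str | Path, format: str = "auto") -> GenotypeMatrix:
    """Load a PLINK fileset as a dosage matrix.

    Parameters
    ----------
    prefix
        Path without extension; ``prefix.ped/.map`` or
        ``prefix.bed/.bim/.fam`` must exist.
    format
        ``"text"``, ``"binary"`` or ``"auto"`` (binary preferred if present).
    """
    prefix = Path(prefix)
    if format == "auto":
        format = "binary" if prefix.with_suffix(".bed").exists() else "text"
    if format == "binary":
        return _read_bed(prefix)
    if format == "text":
        return _read_ped(prefix)
    raise ValueError(f"unknown format {format!r}")


def _read_ped(prefix: Path) -> GenotypeMatrix:
    ped = prefix.with_suffix(".ped")
    mp = prefix.with_suffix(".map")
    for p in (ped, mp):
        if not p.exists():
            raise FileNotFoundError(p)
    map_df = _read_map_file(mp)
    m = len(map_df)
    rows, fids, iids = [], [], []
    with open(ped) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"{ped}: row has {len(parts) - 6} allele fields, expected {2 * m}"
                )
            fids.append(parts[0])
            iids.append(parts[1])
            rows.append(parts[6:])
    alleles = np.array(rows, dtype=object).reshape(len(rows), m, 2)
    a_labels, b_labels = [], []
    calls = np.empty((len(rows), m), dtype=np.int8)
    for j in range(m):
        a, b = _infer_alleles(alleles[:, j, 0], alleles[:, j, 1])
        a_labels.append(a)
        b_labels.append(b)
        pair = alleles[:, j, :]
        miss = (pair == "0").any(axis=1)
        dos = (pair == b).sum(axis=1).astype(np.int8)
        dos[miss] = MISSING
        calls[:, j] = dos
    map_df["allele_a"] = a_labels
    map_df["allele_b"] = b_labels
    mm = MarkerMap(map_df)
    calls = calls[:, mm._sort_order]
    samples = pd.DataFrame({"individual_id": iids, "population": fids})
    return GenotypeMatrix(samples, calls, mm)


def _read_bed(prefix: Path) -> GenotypeMatrix:
    bed = prefix.with_suffix(".bed")
    bim = prefix.with_suffix(".bim")
    fam = prefix.with_suffix(".fam")
    for p in (bed, bim, fam):
        if not p.exists():
            raise FileNotFoundError(p)
    bim_df = pd.read_csv(bim, sep=r"\s+", header=None, dtype=str)
    map_df = pd.DataFrame(
        {
            "chromosome": bim_df[0].astype(int),
            "position": bim_df[3].astype(np.int64),
            "marker_id": bim_df[1],
            "allele_a": bim_df[4],
            "allele_b": bim_df[5],
        }
    )
    fam_df = pd.read_csv(fam, sep=r"\s+", header=None, dtype=str)
    samples = pd.DataFrame({"individual_id": fam_df[1], "population": fam_df[0]})
    n, m = len(samples), len(map_df)
    raw = bed.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f"{bed}: bad magic bytes {raw[:3].hex()} (not PLINK v1 SNP-major)")
    bpm = (n + 3) // 4  # bytes per marker
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != m * bpm:
        raise ValueError(f"{bed}: {body.size} data bytes, expected {m * bpm}")
    calls = _BYTE_LUT[body.reshape(m, bpm)].reshape(m, bpm * 4)[:, :n].T
    mm = MarkerMap(map_df)
    calls = np.ascontiguousarray(calls)[:, mm._sort_order]
    return GenotypeMatrix(samples, calls, mm)


def write_plink(g: GenotypeMatrix, prefix: str | Path, format: str = "binary") -> None:
    """Write ``g`` as a PLINK fileset readable by :func:`read_plink`."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if format == "binary":
        _write_bed(g, prefix)
    elif format == "text":
        _write_ped(g, prefix)
    else:
        raise ValueError(f"unknown format {format!r}")
    _write_sidecar(prefix, g)


def _write_sidecar(prefix: Path, g: GenotypeMatrix) -> None:
    prefix.with_suffix(".log").write_text(
        f"individuals\t{g.n_individuals}\nmarkers\t{g.n_markers}\n"
        f"missing_calls\t{int(g.missing_mask().sum())}\n"
    )


def _map_lines(g: GenotypeMatrix) -> str:
    t = g.map.table
    return "".join(
        f"{c}\t{mid}\t0\t{p}\n"
        for c, mid, p in zip(t["chromosome"], t["marker_id"], t["position"])
    )


def _write_ped(g: GenotypeMatrix, prefix: Path) -> None:
    prefix.with_suffix(".map").write_text(_map_lines(g))
    t = g.map.table
    a = t["allele_a"].to_numpy(dtype=object)
    b = t["allele_b"].to_numpy(dtype=object)
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i in range(g.n_individuals):
            fid = g.samples["population"].iloc[i]
            iid = g.samples["individual_id"].iloc[i]
            fields = [str(fid), str(iid), "0", "0", "0", "-9"]
            row = g.calls[i]
            for j in range(g.n_markers):
                d = row[j]
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [a[j], a[j]]
                elif d == 1:
                    fields += [a[j], b[j]]
                else:
                    fields += [b[j], b[j]]
            fh.write(" ".join(fields) + "\n")


def _write_bed(g: GenotypeMatrix, prefix: Path) -> None:
    t = g.map.table
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for c, mid, p, a, b in zip(
            t["chromosome"], t["marker_id"], t["position"], t["allele_a"], t["allele_b"]
        ):
            fh.write(f"{c}\t{mid}\t0\t{p}\t{a}\t{b}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for i in range(g.n_individuals):
            fh.write(
                f"{g.samples['population'].iloc[i]} "
                f"{g.samples['individual_id'].iloc[i]} 0 0 0 -9\n"
            )
    n, m = g.n_individuals, g.n_markers
    bpm = (n + 3) // 4
    codes = np.empty((m, bpm * 4), dtype=np.uint8)
    codes[:] = 0b01  # pad slots read back as missing and are sliced off
    dosage_code = np.array([0b00, 0b10, 0b11], dtype=np.uint8)
    calls_t = g.calls.T
    packed = np.where(calls_t == MISSING, 0b01, dosage_code[np.clip(calls_t, 0, 2)])
    codes[:, :n] = packed
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    by = (codes.reshape(m, bpm, 4) << shifts).sum(axis=2).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(by.tobytes())


# ---------------------------------------------------------------------------
# Quality control and merging


@dataclass
class QCReport:
    """Before/after counts for each QC step."""

    n_individuals_in: int
    n_markers_in: int
    n_non_autosomal_removed: int
    n_individuals_removed: int
    n_markers_removed: int
    n_individuals_out: int
    n_markers_out: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"count": list(self.__dict__.values())}, index=list(self.__dict__)
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", header=False)


def apply_qc(
    g: GenotypeMatrix,
    max_ind_missing: float = 0.10,
    max_snp_missing: float = 0.05,
    autosomes_only: bool = True,
    autosome_max: int = 29,
) -> tuple[GenotypeMatrix, QCReport]:
    """Call-rate and autosome QC.

    Individuals with missing fraction strictly above ``max_ind_missing`` are
    removed first; then SNPs with missing fraction strictly above
    ``max_snp_missing``, computed on the retained individuals (PLINK's
    --mind/--geno order and strict-inequality semantics). No MAF, HWE or LD
    filtering is applied.
    """
    n_in, m_in = g.n_individuals, g.n_markers
    n_non_auto = 0
    if autosomes_only:
        keep = g.map.chromosomes <= autosome_max
        n_non_auto = int((~keep).sum())
        if n_non_auto:
            g = g.subset_markers(np.flatnonzero(keep))
    if g.n_markers == 0:
        raise ValueError("QC removed all markers (no autosomal markers)")
    miss = g.missing_mask()
    ind_frac = miss.mean(axis=1)
    keep_ind = ind_frac <= max_ind_missing
    if not keep_ind.any():
        raise ValueError("QC removed all individuals")
    g2 = g.subset_individuals(np.flatnonzero(keep_ind))
    snp_frac = g2.missing_mask().mean(axis=0)
    keep_snp = snp_frac <= max_snp_missing
    if not keep_snp.any():
        raise ValueError("QC removed all markers")
    g3 = g2.subset_markers(np.flatnonzero(keep_snp))
    report = QCReport(
        n_individuals_in=n_in,
        n_markers_in=m_in,
        n_non_autosomal_removed=n_non_auto,
        n_individuals_removed=int((~keep_ind).sum()),
        n_markers_removed=int((~keep_snp).sum()),
        n_individuals_out=g3.n_individuals,
        n_markers_out=g3.n_markers,
    )
    logger.info("QC: %s", report.__dict__)
    return g3, report


def merge_panels(panels: list[GenotypeMatrix]) -> GenotypeMatrix:
    """Merge panels on their shared markers, concatenating samples.

    Markers must agree exactly on chromosome, position and allele labels;
    strand reconciliation is not attempted and conflicts raise.
    """
    if len(panels) < 2:
        raise ValueError("need at least two panels to merge")
    common = set(panels[0].map.marker_ids)
    for p in panels[1:]:
        common &= set(p.map.marker_ids)
    if not common:
        raise ValueError("no shared markers across panels")
    ref = panels[0].map.table.set_index("marker_id")
    aligned_calls = []
    for p in panels:
        t = p.map.table
        sel = np.flatnonzero(t["marker_id"].isin(common).to_numpy())
        sub = p.subset_markers(sel)
        st = sub.map.table.set_index("marker_id")
        for mid in st.index:
            r, s = ref.loc[mid], st.loc[mid]
            if (r["allele_a"], r["allele_b"]) != (s["allele_a"], s["allele_b"]):
                raise ValueError(
                    f"allele conflict at marker {mid!r}: "
                    f"({r['allele_a']},{r['allele_b']}) vs ({s['allele_a']},{s['allele_b']})"
                )
            if (r["chromosome"], r["position"]) != (s["chromosome"], s["position"]):
                raise ValueError(f"map conflict at marker {mid!r}")
        aligned_calls.append(sub)
    base_map = aligned_calls[0].map
    order_ids = base_map.marker_ids.to_numpy()
    calls = [aligned_calls[0].calls]
    for sub in aligned_calls[1:]:
        idx = sub.map.marker_ids.reset_index(drop=True)
        pos = pd.Series(np.arange(len(idx)), index=idx)
        calls.append(sub.calls[:, pos.loc[order_ids].to_numpy()])
    samples = pd.concat([p.samples for p in panels], ignore_index=True)
    return GenotypeMatrix(samples, np.vstack(calls), base_map)


# ---------------------------------------------------------------------------
# Oxford phased haplotypes


def read_haps(prefix: str | Path) -> HaplotypePanel:
    """Read an Oxford .haps/.sample pair as a phased haplotype panel.

    The file's 0/1 coding is kept as-is (``ancestral_source`` = "coded");
    use :func:`attach_ancestral` to orient alleles as ancestral/derived.
    """
    prefix = Path(prefix)
    haps_p = prefix.with_suffix(".haps")
    sample_p = prefix.with_suffix(".sample")
    for p in (haps_p, sample_p):
        if not p.exists():
            raise FileNotFoundError(p)
    sample_df = pd.read_csv(sample_p, sep=r"\s+", dtype=str)
    sample_df = sample_df.iloc[1:].reset_index(drop=True)  # drop the "0 0 0" type row
    samples = pd.DataFrame(
        {"individual_id": sample_df.iloc[:, 1], "population": sample_df.iloc[:, 0]}
    )
    chroms, mids, poss, a_lab, b_lab, rows = [], [], [], [], [], []
    with open(haps_p) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            chroms.append(int(parts[0]))
            mids.append(parts[1])
            poss.append(int(parts[2]))
            a_lab.append(parts[3])
            b_lab.append(parts[4])
            alleles = parts[5:]
            if any(a not in ("0", "1") for a in alleles):
                raise ValueError(f"non-binary haplotype symbol in {haps_p}")
            rows.append(np.array(alleles, dtype=np.uint8))
    hap = np.array(rows, dtype=np.uint8).T if rows else np.empty((0, 0), np.uint8)
    if hap.shape[0] % 2 != 0:
        raise ValueError(f"{haps_p}: odd haplotype count {hap.shape[0]}")
    if hap.shape[0] != 2 * len(samples):
        raise ValueError(
            f"{haps_p}: {hap.shape[0]} haplotype columns but "
            f"{len(samples)} samples in {sample_p}"
        )
    mm = MarkerMap(
        pd.DataFrame(
            {
                "chromosome": chroms,
                "position": poss,
                "marker_id": mids,
                "allele_a": a_lab,
                "allele_b": b_lab,
            }
        )
    )
    hap = hap[:, mm._sort_order]
    return HaplotypePanel(hap, mm, samples)


def write_haps(h: HaplotypePanel, prefix: str | Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    t = h.map.table
    with open(prefix.with_suffix(".haps"), "w") as fh:
        for j in range(h.n_markers):
            head = (
                f"{t['chromosome'].iloc[j]} {t['marker_id'].iloc[j]} "
                f"{t['position'].iloc[j]} {t['allele_a'].iloc[j]} {t['allele_b'].iloc[j]}"
            )
            fh.write(head + " " + " ".join(map(str, h.haplotypes[:, j])) + "\n")
    with open(prefix.with_suffix(".sample"), "w") as fh:
        fh.write("ID_1 ID_2 missing\n0 0 0\n")
        for i in range(h.n_individuals):
            fh.write(
                f"{h.samples['population'].iloc[i]} "
                f"{h.samples['individual_id'].iloc[i]} 0\n"
            )


def attach_ancestral(
    h: HaplotypePanel,
    ancestral: dict[str, str] | pd.Series | None = None,
    fallback: str = "major",
) -> HaplotypePanel:
    """Orient haplotype coding so 0 = ancestral allele at every marker.

    Markers listed in ``ancestral`` (marker_id -> allele label) are recoded
    from the table; the remainder either use the sample major allele as
    ancestral (``fallback="major"``, flagged in ``ancestral_source``) or are
    dropped (``fallback="none"``).
    """
    if fallback not in ("major", "none"):
        raise ValueError("fallback must be 'major' or 'none'")
    anc = dict(ancestral) if ancestral is not None else {}
    hap = h.haplotypes.copy()
    table = h.map.table.copy()
    source = np.asarray(h.ancestral_source, dtype=object).copy()
    keep = np.ones(h.n_markers, dtype=bool)
    freq = hap.mean(axis=0)
    for j in range(h.n_markers):
        mid = table["marker_id"].iloc[j]
        a, b = table.loc[j, "allele_a"], table.loc[j, "allele_b"]
        if mid in anc:
            anc_allele = anc[mid]
            if anc_allele not in (a, b):
                raise ValueError(
                    f"ancestral allele {anc_allele!r} for {mid!r} is not among ({a},{b})"
                )
            flip = anc_allele == b
            source[j] = "user"
        elif fallback == "none":
            keep[j] = False
            continue
        else:
            flip = freq[j] > 0.5
            source[j] = "major"
        if flip:
            hap[:, j] = 1 - hap[:, j]
            table.loc[j, ["allele_a", "allele_b"]] = [b, a]
    idx = np.flatnonzero(keep)
    return HaplotypePanel(
        hap[:, idx],
        MarkerMap(table.iloc[idx].reset_index(drop=True)),
        h.samples,
        ancestral_source=source[idx],
    )
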