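"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately naive: exhaustive enumeration and pairwise
comparison, no sharing of code paths with the package.
"""

from __future__ import annotations

import numpy as np

MISSING = -1


def decode_bed_byte(byte: int, n: int) -> list[int]:
    """Bit-level decode of one PLINK .bed byte for up to 4 individuals."""
    out = []
    for k in range(min(n, 4)):
        code = (byte >> (2 * k)) & 0b11
        out.append({0b00: 0, 0b01: MISSING, 0b10: 1, 0b11: 2}[code])
    return out


def roh_oracle(
    calls: np.ndarray,
    pos: np.ndarray,
    min_snp: int,
    min_length_bp: float,
    density_kb: float,
    max_gap_bp: float,
) -> list[tuple[int, int]]:
    """Maximal zero-heterozygote stretches passing the segment filters.

    Enumerates every maximal stretch free of heterozygous calls for one
    individual's chromosome, splits on inter-marker gaps above the cap,
    trims terminal missing calls, and applies the SNP-count, length and
    density filters. Returns (start_index, end_index) pairs.
    """
    n = calls.size
    stretches = []
    i = 0
    while i < n:
        if calls[i] == 1:
            i += 1
            continue
        j = i
        while j + 1 < n and calls[j + 1] != 1:
            j += 1
        stretches.append((i, j))
        i = j + 1
    out = []
    for s, e in stretches:
        # split on oversized gaps
        pieces, a = [], s
        for k in range(s, e):
            if pos[k + 1] - pos[k] > max_gap_bp:
                pieces.append((a, k))
                a = k + 1
        pieces.append((a, e))
        for a, b in pieces:
            while a <= b and calls[a] == MISSING:
                a += 1
            while b >= a and calls[b] == MISSING:
                b -= 1
            if a > b:
                continue
            n_snp = b - a + 1
            length = pos[b] - pos[a] + 1
            if n_snp < min_snp:
                continue
            if length < min_length_bp:
                continue
            if (length / 1000.0) / n_snp > density_kb:
                continue
            out.append((a, b))
    return out


def ehh_oracle(hap: np.ndarray, core: int, allele: int, target: int) -> float:
    """EHH by exhaustive pairwise base-by-base comparison of carriers."""
    carriers = np.flatnonzero(hap[:, core] == allele)
    n = carriers.size
    if n < 2:
        raise ValueError("fewer than two carriers")
    lo, hi = min(core, target), max(core, target)
    same = 0
    for ii in range(n):
        for jj in range(ii + 1, n):
            if np.array_equal(
                hap[carriers[ii], lo : hi + 1], hap[carriers[jj], lo : hi + 1]
            ):
                same += 1
    return 2.0 * same / (n * (n - 1))


def ihh_oracle(
    hap: np.ndarray,
    pos: np.ndarray,
    core: int,
    allele: int,
    cutoff: float,
    max_gap: int,
) -> float:
    """Trapezoid-integrated EHH from the pairwise oracle, both sides."""
    total = 0.0
    for direction in (-1, +1):
        ehh_prev, pos_prev = 1.0, pos[core]
        j = core
        while True:
            j_next = j + direction
            if j_next < 0 or j_next >= pos.size:
                break
            if abs(int(pos[j_next]) - int(pos[j])) > max_gap:
                break
            e = ehh_oracle(hap, core, allele, j_next)
            total += 0.5 * (ehh_prev + e) * abs(int(pos[j_next]) - int(pos_prev))
            ehh_prev, pos_prev = e, pos[j_next]
            if e < cutoff:
                break
            j = j_next
    return total
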