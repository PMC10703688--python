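"""CN-mappability masks and NAHR-eligible homology pairs on desk-scale genomes.

Base-level mappability follows a k-mer uniqueness criterion: a position is
base-unmappable when its k-mer (k = 101 by default) occurs elsewhere in
the genome on either strand, or contains an N.  A position is then
CN-unmappable when more than 90% of the bases in a 1-kb window around it
are base-unmappable (strictly more; exactly 90% stays mappable).

NAHR-eligible homologous position pairs are enumerated exhaustively: all
pairs of 500-bp windows, on both strand phases, matching at >= 96% ungapped
(Hamming) identity and separated by more than 10 kb.  Enumeration is
seed-and-extend (an exact shared seed k-mer must exist by pigeonhole given
<= 20 mismatches in 500 bp), with per-diagonal sliding-window verification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_COMP = str.maketrans("ACGTN", "TGCAN")


def _rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass
class MappabilityMask:
    flags: dict[str, np.ndarray]       # per-base unmappable flags
    k: int = 101
    window: int = 1000
    threshold: float = 0.90

    def cn_unmappable(self) -> dict[str, np.ndarray]:
        return {c: window_unmappable(f, self.window, self.threshold)
                for c, f in self.flags.items()}


def base_mappability(genome: dict[str, str], k: int = 101,
                     max_mismatches: int = 0) -> dict[str, np.ndarray]:
    """Per-base unmappable flags from k-mer uniqueness.

    A position takes the flag of the k-mer starting there (positions within
    k of the contig end share the last full k-mer).  With
    `max_mismatches` > 0, near-duplicate k-mers within that Hamming
    distance also count, found by chunk seeding.
    """
    counts: dict[str, int] = {}
    for chrom, seq in genome.items():
        s = seq.upper()
        if len(s) < k:
            logger.warning("contig %s shorter than k=%d; all unmappable", chrom, k)
            continue
        for i in range(len(s) - k + 1):
            km = s[i:i + k]
            counts[km] = counts.get(km, 0) + 1

    def dup(km: str) -> bool:
        if counts.get(km, 0) >= 2:
            return True
        r = _rc(km)
        return r != km and counts.get(r, 0) >= 1

    flags = {}
    for chrom, seq in genome.items():
        s = seq.upper()
        L = len(s)
        f = np.zeros(L, dtype=bool)
        if L < k:
            f[:] = True
            flags[chrom] = f
            continue
        kmer_flag = np.zeros(L - k + 1, dtype=bool)
        for i in range(L - k + 1):
            km = s[i:i + k]
            kmer_flag[i] = "N" in km or dup(km)
        if max_mismatches > 0:
            kmer_flag |= _near_duplicate_kmers(genome, chrom, k, max_mismatches)
        f[:L - k + 1] = kmer_flag
        f[L - k + 1:] = kmer_flag[-1]
        flags[chrom] = f
    return flags


def _seq_arrays(genome: dict[str, str]):
    return {c: np.frombuffer(s.upper().encode(), dtype=np.uint8)
            for c, s in genome.items()}


def _near_duplicate_kmers(genome, chrom, k, max_mm):
    """k-mers of `chrom` within Hamming distance max_mm of a k-mer elsewhere.

    Reuses the homology window scanner with tract = k.
    """
    hits = np.zeros(len(genome[chrom]) - k + 1, dtype=bool)
    table = enumerate_homology_pairs(
        genome, tract=k, identity=1.0 - max_mm / k, min_sep=0,
        restrict_chrom=chrom, include_self_overlap=False)
    for r in table.itertuples():
        if r.chrom1 == chrom and 0 <= r.pos1 < len(hits):
            hits[r.pos1] = True
    return hits


def window_unmappable(flags: np.ndarray, window: int = 1000,
                      threshold: float = 0.90) -> np.ndarray:
    """CN-unmappable flags: windowed unmappable fraction strictly > threshold.

    Windows are truncated at contig ends and the fraction is computed over
    the available bases.
    """
    L = len(flags)
    half = window // 2
    cs = np.concatenate([[0], np.cumsum(flags.astype(np.int64))])
    lo = np.maximum(np.arange(L) - half, 0)
    hi = np.minimum(np.arange(L) + window - half, L)
    frac = (cs[hi] - cs[lo]) / (hi - lo)
    return frac > threshold


def flags_to_intervals(flags: np.ndarray) -> list[tuple[int, int]]:
    """0-based half-open runs of True."""
    if not len(flags):
        return []
    d = np.diff(flags.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0] + 1)
    if flags[0]:
        starts = [0] + starts
    if flags[-1]:
        ends = ends + [len(flags)]
    return list(zip(starts, ends))


def cn_mappable_intervals(flags: dict[str, np.ndarray], window: int = 1000,
                          threshold: float = 0.90):
    """(CN-unmappable BED rows, CN-mappable BED rows) as DataFrames."""
    un, mp = [], []
    for chrom, f in flags.items():
        w = window_unmappable(f, window, threshold)
        for a, b in flags_to_intervals(w):
            un.append((chrom, a, b))
        for a, b in flags_to_intervals(~w):
            mp.append((chrom, a, b))
    cols = ["chrom", "start", "end"]
    return pd.DataFrame(un, columns=cols), pd.DataFrame(mp, columns=cols)


def _window_pairs_on_diagonal(a1: np.ndarray, a2: np.ndarray, off: int,
                              tract: int, max_mm: int):
    """Window start pairs (p1, p2 = p1 + off) matching with <= max_mm
    mismatches, over the overlap of a1 and a2 shifted by off."""
    lo = max(0, -off)
    hi = min(len(a1), len(a2) - off)
    if hi - lo < tract:
        return []
    mism = (a1[lo:hi] != a2[lo + off:hi + off]).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(mism)])
    n = hi - lo - tract + 1
    counts = cs[tract:tract + n] - cs[:n]
    ok = np.nonzero(counts <= max_mm)[0]
    return [(lo + int(i), lo + int(i) + off) for i in ok]


def enumerate_homology_pairs(genome: dict[str, str], tract: int = 500,
                             identity: float = 0.96, min_sep: int = 10_000,
                             seed_k: int | None = None,
                             restrict_chrom: str | None = None,
                             include_self_overlap: bool = True
                             ) -> pd.DataFrame:
    """All homologous position pairs: `tract`-bp windows at >= identity.

    Returns a symmetric table (both orientations of every pair) with
    columns chrom1, pos1, chrom2, pos2, strand2, identity.  Same-chromosome
    pairs closer than `min_sep` are excluded.
    """
    max_mm = int(np.floor((1.0 - identity) * tract + 1e-9))
    if seed_k is None:
        seed_k = max(12, tract // (max_mm + 1))
    arrs = _seq_arrays(genome)
    rc_arrs = {c: np.frombuffer(_rc(s.upper()).encode(), dtype=np.uint8)
               for c, s in genome.items()}

    seeds: dict[bytes, list[tuple[str, int]]] = {}
    for c, a in arrs.items():
        ab = a.tobytes()
        for i in range(0, len(a) - seed_k + 1):
            seeds.setdefault(ab[i:i + seed_k], []).append((c, i))

    # candidate diagonals: (c1, c2, strand, offset-or-anticonst)
    diags: set[tuple[str, str, str, int]] = set()
    chroms = list(genome)
    for c2 in chroms:
        L2 = len(genome[c2])
        rev = rc_arrs[c2].tobytes()
        for i in range(0, L2 - seed_k + 1):
            km = rev[i:i + seed_k]
            # rc-array index i corresponds to reference window start L2-seed_k-i
            for (c1, p1) in seeds.get(km, []):
                diags.add((c1, c2, "-", i - p1))
    for km, plist in seeds.items():
        for (c1, p1) in plist:
            for (c2, p2) in plist:
                diags.add((c1, c2, "+", p2 - p1))

    pairs = set()
    for c1, c2, strand, off in sorted(diags):
        if restrict_chrom is not None and c1 != restrict_chrom:
            continue
        a1 = arrs[c1]
        a2 = arrs[c2] if strand == "+" else rc_arrs[c2]
        L2 = len(arrs[c2])
        if strand == "+" and c1 == c2 and off == 0:
            continue  # self-diagonal
        for p1, q in _window_pairs_on_diagonal(a1, a2, off, tract, max_mm):
            if strand == "+":
                p2 = q
            else:
                p2 = L2 - q - tract  # reference coordinate of the rc window
            if c1 == c2:
                if strand == "-" and p1 == p2 and not include_self_overlap:
                    continue
                if abs(p1 - p2) <= min_sep:
                    continue
            mm = int(np.sum(a1[p1:p1 + tract] !=
                            (arrs[c2][p2:p2 + tract] if strand == "+"
                             else rc_arrs[c2][L2 - p2 - tract:L2 - p2])))
            ident = 1.0 - mm / tract
            pairs.add((c1, p1, c2, p2, strand, round(ident, 6)))
            pairs.add((c2, p2, c1, p1, strand, round(ident, 6)))

    return pd.DataFrame(sorted(pairs),
                        columns=["chrom1", "pos1", "chrom2", "pos2",
                                 "strand2", "identity"])
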