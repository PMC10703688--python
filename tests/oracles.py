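"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the balance oracle
enumerates every integer assignment instead of solving a MIP, and the
homology/mappability oracles scan all diagonals without seeding.
"""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np

from gbalance.graph import GenomeGraph
from gbalance.mappability import _rc


def enumerate_min_objective(graph: GenomeGraph, lam: float, cap: int) -> float:
    """Exhaustive minimum of the balance objective over integer assignments.

    Enumerates all reference/variant edge CNs in {0..cap} (forced edges
    from 1); for fixed edges, each vertex's optimal CN and loose-end usage
    is independent: kappa(v) ranges over [max(in, out), cap], a side with
    slack pays lambda unless a telomere edge sits there.
    """
    edges = [(eid, e) for eid, e in enumerate(graph.edges)
             if e.kind in ("reference", "variant")]
    n_e = len(edges)
    n_s = len(graph.segments)
    # incidence (segment-side x edge) and telomere flags
    A = np.zeros((2 * n_s, n_e))
    telo = np.zeros(2 * n_s, dtype=bool)
    for i in range(n_s):
        for si, side in enumerate(("L", "R")):
            row = 2 * i + si
            for eid, m in graph.incident(i, side):
                e = graph.edges[eid]
                if e.kind == "telomere":
                    telo[row] = True
                for k, (eid2, _) in enumerate(edges):
                    if eid2 == eid:
                        A[row, k] = m
    lows = [1 if e.forced else 0 for _, e in edges]
    combos = np.array(list(itertools.product(
        *[range(lo, cap + 1) for lo in lows])), dtype=float)
    if combos.size == 0:
        combos = np.zeros((1, 0))
    sums = combos @ A.T  # (C, 2*n_s)
    C = len(combos)
    total = np.zeros(C)
    feasible = np.ones(C, dtype=bool)
    for i, s in enumerate(graph.segments):
        sl, sr = sums[:, 2 * i], sums[:, 2 * i + 1]
        lo = np.maximum(sl, sr)
        feasible &= lo <= cap
        w = s.weight
        rho = s.rho if s.rho is not None else 0.0
        best = np.full(C, np.inf)
        for kappa in range(cap + 1):
            ok = kappa >= lo
            cost = w * abs(rho - kappa) * np.ones(C)
            if not telo[2 * i]:
                cost += lam * (kappa > sl)
            if not telo[2 * i + 1]:
                cost += lam * (kappa > sr)
            cost[~ok] = np.inf
            best = np.minimum(best, cost)
        total += np.where(np.isfinite(best), best, np.inf)
    total[~feasible] = np.inf
    return float(total.min())


def brute_homology_pairs(genome: dict[str, str], tract: int = 500,
                         identity: float = 0.96, min_sep: int = 10_000) -> set:
    """All homologous window pairs by full diagonal scan (no seeding)."""
    max_mm = int(np.floor((1 - identity) * tract + 1e-9))
    arrs = {c: np.frombuffer(s.upper().encode(), np.uint8)
            for c, s in genome.items()}
    rcs = {c: np.frombuffer(_rc(s.upper()).encode(), np.uint8)
           for c, s in genome.items()}
    out = set()
    for c1 in genome:
        for c2 in genome:
            a1 = arrs[c1]
            for strand in "+-":
                a2 = arrs[c2] if strand == "+" else rcs[c2]
                L2 = len(arrs[c2])
                for off in range(-(len(a1) - tract), len(a2) - tract + 1):
                    lo, hi = max(0, -off), min(len(a1), len(a2) - off)
                    if hi - lo < tract:
                        continue
                    if strand == "+" and c1 == c2 and off == 0:
                        continue
                    mism = (a1[lo:hi] != a2[lo + off:hi + off]).astype(np.int32)
                    cs = np.concatenate([[0], np.cumsum(mism)])
                    n = hi - lo - tract + 1
                    cnt = cs[tract:tract + n] - cs[:n]
                    for i in np.nonzero(cnt <= max_mm)[0]:
                        p1 = lo + int(i)
                        q = p1 + off
                        p2 = q if strand == "+" else L2 - q - tract
                        if c1 == c2 and abs(p1 - p2) <= min_sep:
                            continue
                        out.add((c1, p1, c2, p2, strand))
                        out.add((c2, p2, c1, p1, strand))
    return out


def brute_base_unmappable(genome: dict[str, str], k: int = 101) -> dict:
    """Per-base unmappable flags by direct k-mer counting."""
    cnt = Counter()
    for s in genome.values():
        s = s.upper()
        for i in range(len(s) - k + 1):
            cnt[s[i:i + k]] += 1
    out = {}
    for chrom, s in genome.items():
        s = s.upper()
        L = len(s)
        f = np.ones(L, dtype=bool)
        if L >= k:
            for i in range(L - k + 1):
                km = s[i:i + k]
                r = _rc(km)
                f[i] = ("N" in km or cnt[km] >= 2
                        or (r != km and cnt[r] >= 1))
            f[L - k + 1:] = f[L - k]
        out[chrom] = f
    return out
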