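"""Changepoint pre-segmentation of binned depth.

Recursive binary segmentation: each interval is split at the position
maximizing the two-sample t statistic (equivalently, minimizing the
residual sum of squares of a two-mean fit), and a split is kept when it
improves a BIC-style criterion.  Deterministic for fixed input.
"""

from __future__ import annotations

import numpy as np


def _best_split(v: np.ndarray, min_width: int):
    """(index, sse_split, sse_total) of the best two-mean split, or None."""
    n = len(v)
    if n < 2 * min_width:
        return None
    c1 = np.cumsum(v)
    c2 = np.cumsum(v * v)
    tot1, tot2 = c1[-1], c2[-1]
    k = np.arange(min_width, n - min_width + 1)  # left part size
    sl = c1[k - 1]
    s2l = c2[k - 1]
    nl = k
    nr = n - k
    sse_l = s2l - sl * sl / nl
    sr = tot1 - sl
    sse_r = (tot2 - s2l) - sr * sr / nr
    sse = sse_l + sse_r
    i = int(np.argmin(sse))
    sse_tot = tot2 - tot1 * tot1 / n
    return int(k[i]), float(sse[i]), float(sse_tot)


def _best_window(v: np.ndarray, min_width: int, max_width: int):
    """Best embedded window (two-changepoint) split: (i, j, sse, sse_tot).

    Tests interior windows of width min_width..max_width against their
    complement (the circular-segmentation alternative that a single split
    cannot see when a short segment is embedded in a long flat interval).
    """
    n = len(v)
    if n < min_width * 3:
        return None
    cs = np.concatenate([[0.0], np.cumsum(v)])
    tot1 = cs[-1]
    tot2 = float(np.sum(v * v))
    sse_tot = tot2 - tot1 * tot1 / n
    best = None
    hi_w = min(max_width, n - min_width)
    for d in range(min_width, hi_w + 1):
        wsum = cs[d:] - cs[:-d]          # window sums, starts 0..n-d
        starts = np.arange(n - d + 1)
        inner = (starts > 0) & (starts + d < n)  # true interior windows
        if not inner.any():
            continue
        mw = wsum / d
        mc = (tot1 - wsum) / (n - d)
        red = d * (n - d) / n * (mw - mc) ** 2
        red[~inner] = -np.inf
        i = int(np.argmax(red))
        sse = sse_tot - float(red[i])
        if best is None or sse < best[2]:
            best = (i, i + d, sse, sse_tot)
    return best


def segment_values(v: np.ndarray, penalty_mult: float = 4.0,
                   min_width: int = 3, max_window: int = 200) -> list[int]:
    """Changepoint indices (split positions) within a 1-D array.

    Each interval is split either at the best single changepoint or at the
    best embedded window of up to `max_window` points, whichever improves
    the BIC criterion more; accepted splits recurse.
    """
    v = np.asarray(v, dtype=float)
    n_total = len(v)
    if n_total < 2:
        return []
    log_n = np.log(max(n_total, 2))
    out: list[int] = []
    stack = [(0, n_total)]
    while stack:
        a, b = stack.pop()
        n = b - a
        res = _best_split(v[a:b], min_width)
        if res is None:
            continue
        k, sse_split, sse_tot = res
        if sse_tot <= 1e-12:
            continue

        def bic(sse, n_bp):
            if sse <= 1e-12:
                return -np.inf
            return n * np.log(sse / sse_tot) + n_bp * penalty_mult * log_n

        cand = [(bic(sse_split, 1), [k])]
        win = _best_window(v[a:b], min_width, max_window)
        if win is not None:
            i, j, sse_w, _ = win
            cand.append((bic(sse_w, 2), [i, j]))
        score, cuts = min(cand, key=lambda t: t[0])
        if score < 0:
            pts = sorted(cuts)
            out.extend(a + p for p in pts)
            edges = [a] + [a + p for p in pts] + [b]
            for lo, hi in zip(edges[:-1], edges[1:]):
                stack.append((lo, hi))
    return sorted(out)


def segment_depth(profile, penalty_mult: float = 4.0,
                  min_width: int = 3) -> dict[str, list[int]]:
    """Changepoint genomic coordinates per chromosome.

    Masked bins are skipped; a breakpoint is reported at the start
    coordinate of the first bin of the right-hand part.
    """
    out: dict[str, list[int]] = {}
    for chrom, vals in profile.values.items():
        ok = ~np.isnan(vals)
        if ok.sum() < 2:
            out[chrom] = []
            continue
        idx = np.nonzero(ok)[0]
        splits = segment_values(vals[idx], penalty_mult, min_width)
        out[chrom] = [int(idx[s] * profile.bin_width) for s in splits]
    return out
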