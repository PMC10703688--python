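"""Allelic (parental-homolog) mass balance.

A balanced total-CN genome graph is expanded into an allelic graph: every
vertex yields two allelic vertices (parental homologs A and B) and every
edge yields four allelic images (one per ordered homolog assignment of its
endpoints).  Allelic vertex CNs must sum to the vertex total, and the
"infinite sites" assumption restricts edge usage: a variant edge may carry
flow on at most one of its four images, and at most one of the two
incoming (similarly outgoing) reference images of an allelic vertex may be
nonzero -- each junction arose once, on a single homolog.

The allelic CN assignment maximizes a Laplace likelihood of segment-mean
allelic SNP counts (transformed to CN units, scale max(1, sqrt(rho)) as in
the total fit) under these constraints, again as an exact MILP.  Allelic
loose ends absorb flow the constraints cannot route; a loose end
co-located with a fitted total-CN loose end incurs no second penalty.
Crossover between homologs (allelic homologous recombination, AHR) then
surfaces as a reciprocal pair of copy-neutral allelic loose ends on
distinct homologs, because infinite sites forbids both homologs of the
upstream segment feeding one downstream allelic vertex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .graph import LEFT, RIGHT, Breakend, GenomeGraph, insert_boundaries
from .profiles import SnpCounts
from .segmentation import segment_values
from .solver import FitConfig

logger = logging.getLogger(__name__)

HAPS = ("A", "B")


@dataclass
class AllelicLoose:
    seg: int
    side: str
    hap: str
    cn: int
    breakend: Breakend


@dataclass
class AllelicGraph:
    """Fitted per-homolog expansion of a balanced total-CN graph."""

    parent: GenomeGraph
    cn_a: list[int]
    cn_b: list[int]
    images: dict[int, dict[tuple[str, str], int]]  # edge id -> {(h1,h2): cn}
    loose: list[AllelicLoose]
    objective: float
    status: str = "optimal"

    def minor_cn(self, i: int) -> int:
        return min(self.cn_a[i], self.cn_b[i])

    def segment_table(self):
        """(chrom, start, end, total, minor, cn_a, cn_b) per segment."""
        rows = []
        for i, s in enumerate(self.parent.segments):
            rows.append((s.chrom, s.start, s.end, s.cn,
                         self.minor_cn(i), self.cn_a[i], self.cn_b[i]))
        return rows

    def merged_segments(self):
        """Consecutive same-chromosome runs of equal (cn_a, cn_b) fused."""
        rows = []
        for chrom in self.parent.chrom_lengths:
            run = None
            for i in self.parent.chrom_segments(chrom):
                s = self.parent.segments[i]
                key = (self.cn_a[i], self.cn_b[i])
                if run is not None and run[3] == key and run[2] == s.start:
                    run = (run[0], run[1], s.end, key)
                else:
                    if run is not None:
                        rows.append(run)
                    run = (chrom, s.start, s.end, key)
            if run is not None:
                rows.append(run)
        return [(c, a, b, k[0] + k[1], min(k), k[0], k[1])
                for c, a, b, k in rows]


def segment_snp_stats(graph: GenomeGraph, snps: SnpCounts):
    """Per segment: (n_snps, mean CN-unit count per haplotype)."""
    cn = snps.cn_units()
    out = []
    for s in graph.segments:
        sub = cn[(cn["chrom"] == s.chrom) & (cn["pos"] >= s.start)
                 & (cn["pos"] < s.end)]
        if len(sub):
            out.append((len(sub), float(sub["cn_hap1"].mean()),
                        float(sub["cn_hap2"].mean())))
        else:
            out.append((0, np.nan, np.nan))
    return out


def split_minor_allele(graph: GenomeGraph, snps: SnpCounts,
                       min_size: int = 1_000_000, min_snps: int = 10,
                       penalty_mult: float = 4.0, profile=None) -> GenomeGraph:
    """Split large segments at changepoints of the minor allelic count.

    Only segments larger than `min_size` are examined; segments with fewer
    than `min_snps` SNPs are left intact.  Total CN is preserved: children
    inherit the parent CN and new interfaces carry a full-CN reference edge
    plus zero-CN loose-end placeholders.
    """
    t = snps.table
    extra: dict[str, list[int]] = {}
    for s in graph.segments:
        if s.width <= min_size:
            continue
        sub = t[(t["chrom"] == s.chrom) & (t["pos"] >= s.start)
                & (t["pos"] < s.end)].sort_values("pos")
        if len(sub) < min_snps:
            logger.info("segment %s:%d-%d has %d SNPs; not split",
                        s.chrom, s.start, s.end, len(sub))
            continue
        minor = np.minimum(sub["count_hap1"].to_numpy(),
                           sub["count_hap2"].to_numpy()).astype(float)
        pos = sub["pos"].to_numpy()
        for k in segment_values(minor, penalty_mult):
            extra.setdefault(s.chrom, []).append(int(pos[k]))
    if not extra:
        return graph.copy()
    return insert_boundaries(graph, extra, profile)


def balance_allelic(graph: GenomeGraph, snps: SnpCounts,
                    config: FitConfig | None = None,
                    cross_penalty: float = 0.01) -> AllelicGraph:
    """Fit allelic CN on a balanced graph by exact MILP.

    Reference-edge image sums may fall below the parent edge CN only at the
    price of penalized allelic loose ends, which is exactly the AHR
    signature; variant-edge images sum to the parent CN with at most one
    image in use.
    """
    config = config or FitConfig()
    segs = graph.segments
    n_seg = len(segs)
    if any(s.cn is None for s in segs):
        raise ValueError("parent graph must be balanced (CN assigned)")
    cap = max([2] + [s.cn for s in segs]) + 1
    stats = segment_snp_stats(graph, snps)

    # ---- variable layout ------------------------------------------------
    nv = 0

    def new_vars(k):
        nonlocal nv
        out = list(range(nv, nv + k))
        nv += k
        return out

    a_var = new_vars(n_seg)  # homolog-A CN per segment
    img_var: dict[int, dict[tuple[str, str], int]] = {}
    img_bin: dict[int, dict[tuple[str, str], int]] = {}
    tel_var: dict[int, dict[str, int]] = {}
    loose_var: dict[tuple[int, str, str], int] = {}
    loose_bin: dict[tuple[int, str, str], int] = {}
    total_loose_pos = {(e.seg1, e.side1) for _, e in graph.edges_of_kind("loose")
                      if (e.cn or 0) > 0}
    for eid, e in enumerate(graph.edges):
        if e.kind == "telomere":
            tel_var[eid] = {h: new_vars(1)[0] for h in HAPS}
        elif e.kind == "reference" or (e.kind == "variant" and (e.cn or 0) > 0):
            img_var[eid] = {(h1, h2): new_vars(1)[0] for h1 in HAPS for h2 in HAPS}
            img_bin[eid] = {(h1, h2): new_vars(1)[0] for h1 in HAPS for h2 in HAPS}
    for i in range(n_seg):
        for side in (LEFT, RIGHT):
            for h in HAPS:
                loose_var[(i, side, h)] = new_vars(1)[0]
                loose_bin[(i, side, h)] = new_vars(1)[0]
    res_var = {}
    for i, (n_snp, r1, r2) in enumerate(stats):
        if n_snp > 0:
            res_var[i] = (new_vars(1)[0], new_vars(1)[0])

    lb = np.zeros(nv)
    ub = np.full(nv, float(cap))
    integrality = np.ones(nv)
    for i in range(n_seg):
        ub[a_var[i]] = segs[i].cn
    for d in img_bin.values():
        for v in d.values():
            ub[v] = 1.0
    for v in loose_bin.values():
        ub[v] = 1.0
    for i, (va, vb) in res_var.items():
        ub[va] = ub[vb] = np.inf
        integrality[va] = integrality[vb] = 0

    c = np.zeros(nv)
    for i, (va, vb) in res_var.items():
        n_snp, r1, r2 = stats[i]
        c[va] = n_snp / max(1.0, np.sqrt(max(r1, 0.0)))
        c[vb] = n_snp / max(1.0, np.sqrt(max(r2, 0.0)))
    for (i, side, h), v in loose_bin.items():
        if (i, side) not in total_loose_pos:
            c[v] = config.lam
    for eid, e in enumerate(graph.edges):
        if e.kind == "reference" and eid in img_bin:
            c[img_bin[eid][("A", "B")]] += cross_penalty
            c[img_bin[eid][("B", "A")]] += cross_penalty

    rows, cols, vals, clo, cup = [], [], [], [], []
    r = 0

    def add_row(entries, lo, hi):
        nonlocal r
        for col, v in entries:
            rows.append(r)
            cols.append(col)
            vals.append(float(v))
        clo.append(lo)
        cup.append(hi)
        r += 1

    # ---- balance at every (segment, side, homolog) ---------------------
    for i in range(n_seg):
        for side in (LEFT, RIGHT):
            inc = graph.incident(i, side)
            for h in HAPS:
                ent = []
                # kappa_hat(i, h): A -> a_i ; B -> kappa_i - a_i
                ent.append((a_var[i], 1.0 if h == "A" else -1.0))
                rhs = 0.0 if h == "A" else -float(segs[i].cn)
                for eid, m in inc:
                    e = graph.edges[eid]
                    if e.kind == "loose":
                        ent.append((loose_var[(i, side, h)], -1.0))
                    elif e.kind == "telomere":
                        ent.append((tel_var[eid][h], -1.0))
                    elif eid in img_var:
                        for (h1, h2), v in img_var[eid].items():
                            # endpoint-1 of the edge is (e.seg1, e.side1)
                            cnt = 0
                            if (e.seg1, e.side1) == (i, side) and h1 == h:
                                cnt += 1
                            if (e.seg2, e.side2) == (i, side) and h2 == h:
                                cnt += 1
                            if cnt:
                                ent.append((v, -float(cnt)))
                add_row(ent, rhs, rhs)

    # ---- image sums and infinite sites ---------------------------------
    for eid, imgs in img_var.items():
        e = graph.edges[eid]
        ent = [(v, 1.0) for v in imgs.values()]
        if e.kind == "variant":
            add_row(ent, float(e.cn), float(e.cn))
            add_row([(v, 1.0) for v in img_bin[eid].values()], -np.inf, 1.0)
        else:
            add_row(ent, -np.inf, float(e.cn))
            yb = img_bin[eid]
            # at most one incoming image per allelic target vertex,
            # at most one outgoing per allelic source vertex
            add_row([(yb[("A", "A")], 1), (yb[("B", "A")], 1)], -np.inf, 1.0)
            add_row([(yb[("A", "B")], 1), (yb[("B", "B")], 1)], -np.inf, 1.0)
            add_row([(yb[("A", "A")], 1), (yb[("A", "B")], 1)], -np.inf, 1.0)
            add_row([(yb[("B", "A")], 1), (yb[("B", "B")], 1)], -np.inf, 1.0)
        for key, v in imgs.items():
            add_row([(v, 1.0), (img_bin[eid][key], -float(cap))], -np.inf, 0.0)

    for key, v in loose_var.items():
        add_row([(v, 1.0), (loose_bin[key], -float(cap))], -np.inf, 0.0)

    # ---- residual linearization ----------------------------------------
    for i, (va, vb) in res_var.items():
        _, r1, r2 = stats[i]
        # |r1 - a_i|
        add_row([(va, 1.0), (a_var[i], 1.0)], r1, np.inf)
        add_row([(va, 1.0), (a_var[i], -1.0)], -r1, np.inf)
        # |r2 - (kappa_i - a_i)|
        k = float(segs[i].cn)
        add_row([(vb, 1.0), (a_var[i], -1.0)], r2 - k, np.inf)
        add_row([(vb, 1.0), (a_var[i], 1.0)], k - r2, np.inf)

    A = sparse.csr_matrix((vals, (rows, cols)), shape=(r, nv))
    res = milp(c, constraints=LinearConstraint(A, clo, cup),
               integrality=integrality, bounds=Bounds(lb, ub),
               options={"time_limit": config.time_limit,
                        "mip_rel_gap": config.mip_gap})
    if res.x is None:
        raise RuntimeError(f"allelic MIP failed: {res.status} {res.message}")
    x = res.x
    status = "optimal" if res.status == 0 else "incumbent"

    cn_a = [int(round(x[a_var[i]])) for i in range(n_seg)]
    cn_b = [segs[i].cn - cn_a[i] for i in range(n_seg)]
    images = {eid: {key: int(round(x[v])) for key, v in imgs.items()}
              for eid, imgs in img_var.items()}
    loose = []
    for (i, side, h), v in loose_var.items():
        cn = int(round(x[v]))
        if cn > 0:
            loose.append(AllelicLoose(i, side, h, cn, graph.breakend(i, side)))
    return AllelicGraph(graph, cn_a, cn_b, images, loose, float(res.fun or 0.0),
                        status)


def find_ahr_loose_pairs(ag: AllelicGraph, radius: int = 10_000):
    """Reciprocal copy-neutral allelic loose-end pairs on distinct homologs.

    Pairs of fitted allelic loose ends within `radius`, opposite
    orientation, on different parental homologs, with locally constant
    total CN and no fitted total-CN loose end at either breakend.
    """
    g = ag.parent
    total_loose_pos = {(e.seg1, e.side1) for _, e in g.edges_of_kind("loose")
                       if (e.cn or 0) > 0}
    cands = [l for l in ag.loose if (l.seg, l.side) not in total_loose_pos]
    pairs = []
    for i in range(len(cands)):
        for j in range(i + 1, len(cands)):
            l1, l2 = cands[i], cands[j]
            b1, b2 = l1.breakend, l2.breakend
            if (l1.hap == l2.hap or b1.chrom != b2.chrom
                    or b1.strand == b2.strand
                    or abs(b1.pos - b2.pos) > radius):
                continue
            if g.segments[l1.seg].cn != g.segments[l2.seg].cn:
                continue
            pairs.append((l1, l2))
    return pairs
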